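"""Reference benchmark data shipped with the toolkit.

Self-docking RMSD values (Å) for 13 docking protocols re-docking the
co-crystallized reversible inhibitor into the human MAGL X-ray structure
(PDB 5ZUN). The table is the standard input for threshold-based protocol
selection: protocols with RMSD strictly below 2.0 Å against the
crystallographic pose are considered validated.
"""

SELF_DOCKING_RMSD_5ZUN: dict[str, float] = {
    "Autodock 4.2": 1.5,
    "Dock6": 0.5,
    "Fred": 3.8,
    "Glamdock": 1.3,
    "Glide SP": 0.6,
    "Glide XP": 1.5,
    "Gold ASP": 1.4,
    "Gold Chemscore": 3.1,
    "Gold Goldscore": 0.6,
    "Gold PLP": 0.7,
    "Plants": 3.2,
    "rDock": 1.6,
    "Vina": 9.4,
}

#: The six protocols whose self-docked poses also reproduced every key
#: binding-site interaction, used downstream for pose consensus.
CONSENSUS_METHODS: list[str] = [
    "Dock6",
    "Glamdock",
    "Glide SP",
    "Gold ASP",
    "Gold PLP",
    "Gold Goldscore",
]

SELF_DOCKING_THRESHOLD: float = 2.0
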
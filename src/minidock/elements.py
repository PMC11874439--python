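"""Element tables: van der Waals and covalent radii, interaction-type vocabulary.

Radii are a fixed built-in table so the package is self-contained at runtime.
vdW radii follow the Vina/smina lineage conventions; covalent radii are the
standard Cordero single-bond values (rounded to 2 decimals).
"""

from __future__ import annotations

# Interaction types: a reduced 13-type scheme sufficient for the five empirical
# scoring terms and the CNN channel layout (each type x {receptor, ligand}).
INTERACTION_TYPES = (
    "HydrophobicC",
    "NonHydrophobicC",
    "DonorN",
    "AcceptorN",
    "DonorAcceptorN",
    "DonorO",
    "AcceptorO",
    "DonorAcceptorO",
    "S",
    "P",
    "Halogen",
    "Metal",
    "H",
)

HBOND_DONOR_TYPES = frozenset(
    {"DonorN", "DonorAcceptorN", "DonorO", "DonorAcceptorO"}
)
HBOND_ACCEPTOR_TYPES = frozenset(
    {"AcceptorN", "DonorAcceptorN", "AcceptorO", "DonorAcceptorO"}
)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

# vdW radii in Angstrom (used by the surface-distance definition of the
# empirical score and as Gaussian density radii in the gridder).
VDW_RADII = {
    "C": 1.9,
    "N": 1.8,
    "O": 1.7,
    "S": 2.0,
    "P": 2.1,
    "F": 1.8,
    "Cl": 1.9,
    "Br": 2.0,
    "I": 2.0,
    "H": 1.0,
}
VDW_METAL = 1.2  # any element not listed above is treated as metal-like

# Covalent radii in Angstrom (Cordero et al. single-bond radii).
COVALENT_RADII = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
    "Na": 1.66,
    "Mg": 1.41,
    "K": 2.03,
    "Ca": 1.76,
    "Mn": 1.39,
    "Fe": 1.32,
    "Co": 1.26,
    "Ni": 1.24,
    "Cu": 1.32,
    "Zn": 1.22,
}
COVALENT_DEFAULT = 1.4


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, VDW_METAL)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element, COVALENT_DEFAULT)
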
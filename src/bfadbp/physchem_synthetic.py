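"""Synthetic stand-in physicochemical property table (version-pinned).

The encoder needs 14 amino-acid property scales: net charge, hydrophobicity,
hydrophilicity, polarity, polarizability, solvation free energy, graph shape
index, transfer free energy, amino acid composition, correlation coefficient
in regression analysis, residue accessible surface area, partition
coefficient, entropy of formation, and pKa of side chain.

The exact numeric scales behind those names are scattered across the
primary literature and are not bundled with any installed library, so this
module ships a SYNTHETIC stand-in table: values assembled from the standard
scale families commonly used for each property name (Kyte-Doolittle
hydrophobicity, Hopp-Woods hydrophilicity, Grantham polarity, Chothia
accessible surface areas, Fauchere-Pliska partition coefficients, ...),
in their natural units.  It is adequate for exercising the encoder and the
downstream selection machinery, and every test in this package is written
to be table-agnostic: tests pin ``TABLE_VERSION``, not particular numbers.
Swap in a curated table by constructing a ``PhysicochemicalTable`` from your
own mapping.
"""

from __future__ import annotations

TABLE_VERSION = "synthetic-1.0"

#: residue order of the value tuples below
_AA = "ACDEFGHIKLMNPQRSTVWY"

# fmt: off
RAW_SCALES: dict[str, dict[str, float]] = {
    "net charge": dict(zip(_AA, (
        0.0, 0.0, -1.0, -1.0, 0.0, 0.0, 0.1, 0.0, 1.0, 0.0,
        0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0))),
    "hydrophobicity": dict(zip(_AA, (            # Kyte-Doolittle family
        1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
        1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3))),
    "hydrophilicity": dict(zip(_AA, (            # Hopp-Woods family
        -0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
        -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3))),
    "polarity": dict(zip(_AA, (                  # Grantham family
        8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
        5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2))),
    "polarizability": dict(zip(_AA, (            # Charton-Charton family
        0.046, 0.128, 0.105, 0.151, 0.290, 0.000, 0.230, 0.186, 0.219, 0.186,
        0.221, 0.134, 0.131, 0.180, 0.291, 0.062, 0.108, 0.140, 0.409, 0.298))),
    "solvation free energy": dict(zip(_AA, (     # Eisenberg-McLachlan family
        0.67, 0.38, -1.21, -2.02, 2.87, 0.00, 0.64, 1.90, -0.57, 1.90,
        2.40, -0.60, 1.20, -0.22, -2.10, 0.01, 0.52, 1.50, 2.60, 2.30))),
    "graph shape index": dict(zip(_AA, (         # Fauchere et al. family
        1.28, 1.77, 1.60, 1.56, 2.94, 0.00, 2.99, 4.19, 1.89, 2.59,
        2.35, 1.60, 2.67, 1.56, 2.34, 1.31, 3.03, 3.67, 3.21, 2.94))),
    "transfer free energy": dict(zip(_AA, (      # Janin family
        0.3, 0.9, -0.6, -0.7, 0.5, 0.3, -0.1, 0.7, -1.8, 0.5,
        0.4, -0.5, -0.3, -0.7, -1.4, -0.1, -0.2, 0.6, 0.3, -0.4))),
    "amino acid composition": dict(zip(_AA, (    # % occurrence in proteins
        8.3, 1.7, 5.3, 6.2, 3.9, 7.2, 2.2, 5.2, 5.7, 9.0,
        2.4, 4.4, 5.1, 4.0, 5.7, 6.9, 5.8, 6.6, 1.3, 3.2))),
    "correlation coefficient in regression analysis": dict(zip(_AA, (
        0.96, 0.42, 0.42, 0.53, 0.59, 0.61, 0.57, 0.84, 0.73, 0.92,
        0.86, 0.39, 0.61, 0.80, 0.77, 0.53, 0.54, 0.85, 0.58, 0.72))),
    "residue accessible surface area": dict(zip(_AA, (   # Chothia family, A^2
        115.0, 135.0, 150.0, 190.0, 210.0, 75.0, 195.0, 175.0, 200.0, 170.0,
        185.0, 160.0, 145.0, 180.0, 225.0, 115.0, 140.0, 155.0, 255.0, 230.0))),
    "partition coefficient": dict(zip(_AA, (     # Fauchere-Pliska pi family
        0.31, 1.54, -0.77, -0.64, 1.79, 0.00, 0.13, 1.80, -0.99, 1.70,
        1.23, -0.60, 0.72, -0.22, -1.01, -0.04, 0.26, 1.22, 2.25, 0.96))),
    "entropy of formation": dict(zip(_AA, (      # per-residue formation entropy
        29.2, 33.0, 37.1, 41.1, 48.5, 23.7, 43.3, 45.0, 47.3, 43.8,
        44.2, 38.3, 38.0, 44.0, 56.7, 32.4, 35.7, 40.4, 56.9, 51.7))),
    "pKa of side chain": dict(zip(_AA, (         # 0 = no ionisable side chain
        0.0, 8.3, 3.65, 4.25, 0.0, 0.0, 6.0, 0.0, 10.53, 0.0,
        0.0, 0.0, 0.0, 0.0, 12.48, 0.0, 0.0, 0.0, 0.0, 10.07))),
}
# fmt: on

PROPERTY_NAMES: tuple[str, ...] = tuple(RAW_SCALES)
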
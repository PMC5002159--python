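"""Encode a protein into the fixed 46-dimensional feature vector.

Three blocks, concatenated in a fixed order:

* 20 evolutionary-conservation features.  For each amino-acid type the
  log-odds scores of that residue's own PSSM column are summed over the
  positions where the residue occurs,

      P_n = sum_m E[m, n] * [R_m == a_n],

  then squashed to (0, 1) with the standard logistic 1/(1 + e^-P) to
  remove sequence-length effects.

* 12 secondary-structure motif features.  Per-residue H/E/C labels are
  taken as the argmax of the PSIPRED probabilities, collapsed into maximal
  same-type segments, and every window of 3 consecutive segments is
  binned into one of the 12 ordered type triples with distinct adjacent
  types (HEH, HEC, HCH, ... — adjacent types are always distinct by the
  maximal-run construction, so 3*2*2 = 12 categories exhaust the
  possibilities).  Counts are divided by the number of windows.

* 14 physicochemical features: for each property scale, the mean scale
  value over the sequence, logistic-squashed like the conservation block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import physchem_synthetic
from .profile_io import (
    STANDARD_AA,
    SS_ORDER,
    PSSMProfile,
    ProteinRecord,
    SSProbMatrix,
    ValidationError,
)

#: Output order of the conservation block: one feature per amino acid.
CONSERVATION_AA_ORDER = STANDARD_AA

#: The 12 motif categories: ordered (a, b, c) triples over {H, E, C} with
#: a != b and b != c, enumerated in H, E, C priority order.
MOTIF_TRIPLES: tuple[str, ...] = tuple(
    a + b + c
    for a, b, c in itertools.product(SS_ORDER, repeat=3)
    if a != b and b != c
)

#: Block widths of the assembled vector: conservation | motifs | physchem.
BLOCK_WIDTHS = (20, 12, 14)
N_FEATURES = sum(BLOCK_WIDTHS)


class ContractError(ValueError):
    """A caller violated an interface contract (wrong block length etc.)."""


def logistic(p: np.ndarray | float) -> np.ndarray | float:
    """The standard logistic map 1 / (1 + e^-p), onto (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(p, dtype=float)))


@dataclass(frozen=True)
class PhysicochemicalTable:
    """14 named amino-acid property scales.

    ``scales`` holds the raw values in their natural units; ``standardize``
    (default on) re-centres each scale to mean 0 / SD 1 across the 20
    residues before use, so that per-sequence means fall in the logistic
    map's responsive range instead of saturating at 0 or 1.
    """

    scales: Mapping[str, Mapping[str, float]]
    version: str
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.scales) != 14:
            raise ValidationError(
                f"physicochemical table needs exactly 14 properties, got {len(self.scales)}"
            )
        for name, scale in self.scales.items():
            missing = set(STANDARD_AA) - set(scale)
            if missing:
                raise ValidationError(
                    f"property {name!r} missing residues {sorted(missing)}"
                )

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self.scales)

    def as_matrix(self) -> np.ndarray:
        """(14, 20) matrix of scale values, residues in STANDARD_AA order."""
        mat = np.array(
            [[self.scales[p][aa] for aa in STANDARD_AA] for p in self.scales],
            dtype=float,
        )
        if self.standardize:
            mu = mat.mean(axis=1, keepdims=True)
            sd = mat.std(axis=1, keepdims=True)
            sd[sd == 0.0] = 1.0
            mat = (mat - mu) / sd
        return mat


def default_table() -> PhysicochemicalTable:
    """The table shipped with the package (see its module docstring)."""
    return PhysicochemicalTable(
        scales=physchem_synthetic.RAW_SCALES,
        version=physchem_synthetic.TABLE_VERSION,
    )


@dataclass(frozen=True)
class SegmentString:
    """Maximal same-type runs of a secondary-structure label string."""

    segments: tuple[tuple[str, int], ...]  # (type in {H,E,C}, run length >= 1)

    def __post_init__(self) -> None:
        for kind, length in self.segments:
            if kind not in SS_ORDER or length < 1:
                raise ValidationError(f"bad segment ({kind!r}, {length})")
        for (a, _), (b, _) in zip(self.segments, self.segments[1:]):
            if a == b:
                raise ValidationError(
                    "consecutive segments share a type; runs must be maximal"
                )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)

    @property
    def type_string(self) -> str:
        return "".join(kind for kind, _ in self.segments)


@dataclass(frozen=True)
class FeatureVector:
    """The assembled 46-dimensional descriptor for one protein."""

    record_id: str
    values: np.ndarray  # (46,) floats in [0, 1]
    block_widths: tuple[int, int, int] = BLOCK_WIDTHS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_FEATURES,):
            raise ContractError(
                f"feature vector must have length {N_FEATURES}, got {values.shape}"
            )
        if np.any(values < 0.0) or np.any(values > 1.0):
            raise ValidationError("feature values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def conservation(self) -> np.ndarray:
        return self.values[: self.block_widths[0]]

    @property
    def motifs(self) -> np.ndarray:
        a = self.block_widths[0]
        return self.values[a : a + self.block_widths[1]]

    @property
    def physicochemical(self) -> np.ndarray:
        return self.values[self.block_widths[0] + self.block_widths[1] :]


def conservation_features(record: ProteinRecord, pssm: PSSMProfile) -> np.ndarray:
    """Per-amino-acid conservation sums, logistic-normalised.

    For each amino-acid type ``a`` (in :data:`CONSERVATION_AA_ORDER`) the
    PSSM entries E[m, a] are summed over the positions m where the sequence
    carries ``a``; an amino acid absent from the sequence contributes an
    empty sum, hence the neutral value logistic(0) = 0.5.
    """
    if pssm.record_id != record.id:
        raise ContractError(
            f"PSSM for {pssm.record_id!r} paired with record {record.id!r}"
        )
    if pssm.scores.shape[0] != record.L:
        raise ContractError("PSSM row count does not match sequence length")
    sums = np.zeros(20, dtype=float)
    for out_idx, aa in enumerate(CONSERVATION_AA_ORDER):
        col = pssm.column_of(aa)
        positions = [m for m, res in enumerate(record.sequence) if res == aa]
        sums[out_idx] = pssm.scores[positions, col].sum() if positions else 0.0
    return logistic(sums)


def assign_ss_labels(ss: SSProbMatrix) -> str:
    """Argmax H/E/C label per residue; ties resolved by priority H > E > C.

    The internal column order is (H, E, C), so ``argmax`` returning the
    first maximal column implements the priority directly.
    """
    idx = np.argmax(ss.probs, axis=1)
    return "".join(SS_ORDER[i] for i in idx)


def segment(labels: str) -> SegmentString:
    """Collapse a label string into maximal same-type runs."""
    if not labels:
        raise ContractError("empty label string")
    runs = [(kind, len(list(group))) for kind, group in itertools.groupby(labels)]
    return SegmentString(segments=tuple(runs))


def motif_features(segs: SegmentString, normalize: bool = True) -> np.ndarray:
    """Counts of 3-segment motif windows, one slot per category.

    A window is 3 consecutive segments; its type triple indexes one of the
    12 categories in :data:`MOTIF_TRIPLES`.  With ``normalize`` (the
    default) counts are divided by the number of windows, so the vector
    sums to 1 whenever at least 3 segments exist; with fewer than 3
    segments the vector is all zeros either way.
    """
    types = segs.type_string
    counts = np.zeros(len(MOTIF_TRIPLES), dtype=float)
    n_windows = len(types) - 2
    if n_windows < 1:
        return counts
    slot = {triple: i for i, triple in enumerate(MOTIF_TRIPLES)}
    for start in range(n_windows):
        counts[slot[types[start : start + 3]]] += 1.0
    if normalize:
        counts /= n_windows
    return counts


def physicochemical_features(
    record: ProteinRecord, table: PhysicochemicalTable | None = None
) -> np.ndarray:
    """Raw per-property means over the sequence (14 values, natural scale).

    These are the un-squashed block values; :func:`assemble` applies the
    logistic map so all three blocks share the [0, 1] codomain.
    """
    table = table if table is not None else default_table()
    mat = table.as_matrix()  # (14, 20)
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    cols = np.array([aa_index[res] for res in record.sequence])
    return mat[:, cols].mean(axis=1)


def assemble(
    conservation: Sequence[float],
    motifs: Sequence[float],
    physchem: Sequence[float],
    record_id: str = "",
) -> FeatureVector:
    """Concatenate the three blocks into the final descriptor.

    The conservation block arrives already logistic-mapped and the motif
    fractions are already in [0, 1]; the raw physicochemical means are
    passed through the logistic here so every descriptor shares the [0, 1]
    interval.
    """
    conservation = np.asarray(conservation, dtype=float)
    motifs = np.asarray(motifs, dtype=float)
    physchem = np.asarray(physchem, dtype=float)
    for block, width, name in (
        (conservation, 20, "conservation"),
        (motifs, 12, "motif"),
        (physchem, 14, "physicochemical"),
    ):
        if block.shape != (width,):
            raise ContractError(
                f"{name} block must have length {width}, got {block.shape}"
            )
    values = np.concatenate([conservation, motifs, logistic(physchem)])
    return FeatureVector(record_id=record_id, values=values)


def encode_protein(
    record: ProteinRecord,
    pssm: PSSMProfile,
    ss: SSProbMatrix,
    table: PhysicochemicalTable | None = None,
) -> FeatureVector:
    """Full pipeline: (record, PSSM, ss2) triple -> 46-dim FeatureVector."""
    cons = conservation_features(record, pssm)
    motifs = motif_features(segment(assign_ss_labels(ss)))
    phys = physicochemical_features(record, table)
    return assemble(cons, motifs, phys, record_id=record.id)


def feature_names() -> list[str]:
    """Human-readable names for the 46 feature slots, in vector order."""
    table = default_table()
    return (
        [f"cons_{aa}" for aa in CONSERVATION_AA_ORDER]
        + [f"motif_{t}" for t in MOTIF_TRIPLES]
        + [f"phys_{name.replace(' ', '_')}" for name in table.property_names]
    )


def write_feature_csv(path, vectors: Sequence[FeatureVector], labels=None) -> None:
    """Write feature vectors as a headered CSV: id, f001..f0NN[, label]."""
    import pandas as pd

    n = len(vectors[0].values) if vectors else N_FEATURES
    frame = pd.DataFrame(
        [v.values for v in vectors], columns=[f"f{i + 1:03d}" for i in range(n)]
    )
    frame.insert(0, "id", [v.record_id for v in vectors])
    if labels is not None:
        frame["label"] = list(labels)
    frame.to_csv(path, index=False)


def read_feature_csv(path):
    """Read a feature CSV back as (ids, X, labels-or-None)."""
    import pandas as pd

    frame = pd.read_csv(path)
    ids = frame["id"].astype(str).tolist()
    labels = frame["label"].to_numpy(dtype=int) if "label" in frame else None
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    return ids, frame[fcols].to_numpy(dtype=float), labels
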
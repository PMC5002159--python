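"""Synthetic test inputs: file triples and planted-feature datasets.

Everything here is generated programmatically from a seed, so the whole
package builds and tests without downloading sequence databases or running
PSI-BLAST/PSIPRED.  Two kinds of fixture:

* mutually consistent (FASTA, ASCII PSSM, .ss2) file triples in the exact
  dialects the parsers consume;
* labelled classification datasets with a known subset of informative
  features (Gaussian mean-shift planting), the ground truth against which
  feature-selection recovery is scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .bfa import BitArray
from .features import logistic
from .pipeline import DEFAULT_OMEGA, FireflyLayout, fitness
from .profile_io import STANDARD_AA, PSSMProfile, ProteinRecord, SSProbMatrix

#: PSSM column header order used by PSI-BLAST ASCII output
PSSM_HEADER_ORDER = "ARNDCQEGHILKMFPSTWYV"


def write_pssm(record: ProteinRecord, scores: np.ndarray) -> str:
    """Render an L x 20 integer matrix in the PSI-BLAST ASCII dialect.

    ``scores`` columns follow :data:`PSSM_HEADER_ORDER`.  The percentage
    block is filled with zeros and the trailing statistics are emitted so
    the output exercises the same layout real files have.
    """
    scores = np.asarray(scores, dtype=int)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(PSSM_HEADER_ORDER * 2),
    ]
    for m, (res, row) in enumerate(zip(record.sequence, scores), start=1):
        log_odds = " ".join(f"{v:3d}" for v in row)
        percentages = " ".join("  0" for _ in range(20))
        lines.append(f"{m:5d} {res}  {log_odds}  {percentages}  0.00 0.00")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1347     0.3179"]
    return "\n".join(lines) + "\n"


def write_ss2(record: ProteinRecord, probs_hec: np.ndarray) -> str:
    """Render an L x 3 (H, E, C) matrix in PSIPRED VFORMAT.

    Probabilities are printed with 3 decimals in the file's native
    (C, H, E) column order; the per-residue label column is the argmax
    with H > E > C priority.
    """
    probs_hec = np.asarray(probs_hec, dtype=float)
    lines = ["# PSIPRED VFORMAT (synthetic fixture)", ""]
    for i, (res, (p_h, p_e, p_c)) in enumerate(
        zip(record.sequence, probs_hec), start=1
    ):
        label = "HEC"[int(np.argmax([p_h, p_e, p_c]))]
        lines.append(f"{i:4d} {res} {label}   {p_c:.3f}  {p_h:.3f}  {p_e:.3f}")
    return "\n".join(lines) + "\n"


def gen_protein_triple(
    length: int,
    seed: int = 0,
    record_id: str = "syn1",
    ss_labels: str | None = None,
) -> tuple[str, str, str]:
    """A mutually consistent (FASTA, PSSM, ss2) text triple.

    The sequence is drawn uniformly from the 20 standard residues, PSSM
    scores uniformly from [-10, 10], and ss2 rows are random distributions
    rounded to 3 decimals (summing to 1 within the parsers' tolerance).
    ``ss_labels`` optionally forces the per-residue argmax secondary
    structure, which lets callers plant specific motif patterns.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if ss_labels is not None and len(ss_labels) != length:
        raise ValueError("ss_labels must match length")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list(STANDARD_AA), size=length))
    record = ProteinRecord(id=record_id, sequence=sequence)

    scores = rng.integers(-10, 11, size=(length, 20))

    probs = rng.dirichlet(np.ones(3), size=length)  # (H, E, C)
    if ss_labels is not None:
        probs = np.full((length, 3), 0.1)
        for i, lab in enumerate(ss_labels):
            probs[i, "HEC".index(lab)] = 0.8
    probs = np.round(probs, 3)

    fasta_text = f">{record_id}\n{sequence}\n"
    return fasta_text, write_pssm(record, scores), write_ss2(record, probs)


def triple_objects(
    length: int, seed: int = 0, record_id: str = "syn1", ss_labels: str | None = None
) -> tuple[ProteinRecord, PSSMProfile, SSProbMatrix]:
    """In-memory equivalent of :func:`gen_protein_triple` (no file I/O)."""
    import tempfile
    from pathlib import Path

    from . import profile_io

    fasta, pssm, ss2 = gen_protein_triple(length, seed, record_id, ss_labels)
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(tmp)
        (base / "f.fasta").write_text(fasta)
        (base / "p.pssm").write_text(pssm)
        (base / "s.ss2").write_text(ss2)
        record = profile_io.parse_fasta(base / "f.fasta")[0]
        profile = profile_io.parse_pssm(base / "p.pssm", record)
        ssmat = profile_io.parse_ss2(base / "s.ss2", record)
    return record, profile, ssmat


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Recipe for a two-class dataset with known informative features.

    ``informative`` features differ between classes by a standardized mean
    shift ``delta_sep`` on unit-variance Gaussian noise; all other
    features are identically distributed across classes.  Values are
    logistic-squashed so rows obey the [0, 1] feature-vector convention.
    """

    n_per_class: int = 100
    n_features: int = 30
    informative: tuple[int, ...] = (0, 1, 2, 3, 4)
    delta_sep: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        idx = self.informative
        if len(set(idx)) != len(idx):
            raise ValueError("informative indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_features):
            raise ValueError("informative index out of range")
        if self.n_per_class < 1:
            raise ValueError("need at least one sample per class")

    @property
    def truth_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_features, dtype=bool)
        mask[list(self.informative)] = True
        return mask


def gen_planted_dataset(spec: PlantedDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the (X, y) matrix described by ``spec`` (pure in the seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    X = rng.standard_normal((2 * n, spec.n_features))
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    for j in spec.informative:
        X[y == 1, j] += spec.delta_sep
    return np.asarray(logistic(X)), y


def planted_objective(
    spec: PlantedDatasetSpec,
    t: int = 10,
    omega: float = DEFAULT_OMEGA,
    eval_seed: int = 0,
) -> tuple[Callable[[BitArray], float], FireflyLayout, np.ndarray, np.ndarray]:
    """Wrap the SVM fitness over a planted dataset for BFA runs.

    Returns (objective, layout, X, y); the ground-truth informative mask is
    ``spec.truth_mask``, enabling precision/recall scoring of whatever mask
    the search selects.
    """
    X, y = gen_planted_dataset(spec)
    layout = FireflyLayout(t=t, w=spec.n_features)

    def objective(bits: BitArray) -> float:
        return fitness(bits, layout, X, y, omega=omega, eval_seed=eval_seed).intensity

    return objective, layout, X, y


def mask_recovery(selected: Sequence[bool], truth: Sequence[bool]) -> tuple[float, float]:
    """(precision, recall) of a selected feature mask against ground truth."""
    selected = np.asarray(selected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n_sel = int(selected.sum())
    n_true = int(truth.sum())
    hit = int((selected & truth).sum())
    precision = hit / n_sel if n_sel else 0.0
    recall = hit / n_true if n_true else 0.0
    return precision, recall
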
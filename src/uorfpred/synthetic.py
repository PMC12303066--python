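"""Seeded generators for 5'UTRs with planted features and labeled datasets.

These generators stand in for external sequence databases and published
ribosome-profiling tables.  ``random_utr`` builds a 5'UTR whose extracted
features are known by construction: an ATG-free background at a target GC
content, with uORFs spliced in at spaced positions — terminated ones with
an explicit in-frame stop, open ones with their reading frame scrubbed of
stops through the 5'UTR end.  A nonzero Atf4-like target places the open
uORFs downstream of the terminated ones, mimicking ATF4's architecture.

``simulate_labeled`` draws feature vectors and Bernoulli labels from a
known coefficient set, for parameter-recovery checks; the expression-table
generators emit rows spanning every filter region together with the label
the filter is expected to assign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import MIN_UORF_SPACING, STOP_CODONS
from .io import UTRRecord
from .model import CoefficientSet, interaction_design

_SPACING = MIN_UORF_SPACING + 4  # planted AUG starts; > 30 in every frame


class InfeasibleSpecError(ValueError):
    """The requested feature structure cannot fit in the requested length."""


@dataclass(frozen=True)
class UTRSpec:
    """Target structure of one synthetic 5'UTR."""

    length: int
    gc_target: float
    n_uorfs: int
    atf4like_target: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.gc_target <= 100):
            raise InfeasibleSpecError("gc_target must be in [0, 100]")
        if self.atf4like_target > min(3, self.n_uorfs):
            raise InfeasibleSpecError(
                "atf4like_target cannot exceed min(3, n_uorfs)"
            )
        if self.atf4like_target >= 1 and self.n_uorfs < self.atf4like_target + 1:
            raise InfeasibleSpecError(
                "a nonzero Atf4-like count needs at least one terminated uORF "
                "preceding the open ones (n_uorfs >= atf4like_target + 1)"
            )
        if self.length < _min_length(self.n_uorfs):
            raise InfeasibleSpecError(
                f"length {self.length} too short for {self.n_uorfs} uORFs; "
                f"need at least {_min_length(self.n_uorfs)} nt"
            )


def _min_length(n_uorfs: int) -> int:
    if n_uorfs == 0:
        return 0
    # leading context + spaced starts + room for the last uORF's stop
    return 3 + (n_uorfs - 1) * _SPACING + 12


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for a simulated labeled feature dataset."""

    n: int
    beta: CoefficientSet
    seed: int
    a_range: tuple[int, int] = (1, 6)
    b_max: int = 3
    c_range: tuple[int, int] = (20, 600)
    d_range: tuple[float, float] = (30.0, 80.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.a_range[0] < 1:
            raise ValueError("training examples require at least one uORF")


def _random_background(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """ATG-free random sequence at roughly the target GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = "ACGT"
    seq: list[str] = []
    for _ in range(n):
        b = bases[rng.choice(4, p=p)]
        while len(seq) >= 2 and seq[-2] == "A" and seq[-1] == "T" and b == "G":
            b = bases[rng.choice(4, p=p)]
        seq.append(b)
    return seq


def random_utr(spec: UTRSpec, gene_id: str = "synthetic") -> UTRRecord:
    """Generate a 5'UTR whose computed features match the spec.

    The planted structure guarantees A = ``n_uorfs``, B =
    ``atf4like_target`` and C = ``length`` exactly, and D within about 5
    percentage points of ``gc_target``; identical specs yield identical
    sequences.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    seq = _random_background(rng, L, spec.gc_target / 100.0)
    protected: set[int] = set()

    def write(pos: int, text: str) -> None:
        for k, ch in enumerate(text):
            seq[pos + k] = ch
            protected.add(pos + k)

    n_open = spec.atf4like_target
    n_term = spec.n_uorfs - n_open
    starts = [3 + i * _SPACING for i in range(spec.n_uorfs)]
    open_frames = list(range(n_open))  # distinct frames for open uORFs

    for i, p in enumerate(starts[:n_term]):
        write(p - 3, "A")          # Kozak -3 purine
        write(p, "ATGGCCTAA")      # start, filler codon, stop (+4 is G)
    open_starts = []
    for j, f in enumerate(open_frames):
        p = starts[n_term + j]
        p += (f - p) % 3           # shift into the requested frame
        open_starts.append(p)
        write(p - 3, "A")
        write(p, "ATG")
        if p + 3 < L:
            write(p + 3, "G")      # Kozak +4

    def scrub(pos: int) -> None:
        # neutralize a 3-mer by rewriting one unprotected base to C
        for k in (2, 1, 0):
            if pos + k not in protected:
                seq[pos + k] = "C"
                return
        raise AssertionError("motif fully inside planted content")

    # open frames must carry no in-frame stop through the 5'UTR end
    for p in open_starts:
        for q in range(p + 3, L - 2, 3):
            if "".join(seq[q : q + 3]) in STOP_CODONS:
                scrub(q)
    # remove stray ATGs created at planting junctions
    changed = True
    while changed:
        changed = False
        planted_atgs = set(starts[:n_term]) | set(open_starts)
        for i in range(L - 2):
            if (
                seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G"
                and i not in planted_atgs
            ):
                scrub(i)
                changed = True

    _tune_gc(seq, protected, spec.gc_target, open_starts, rng)
    return UTRRecord(gene_id=gene_id, sequence="".join(seq))


def _tune_gc(
    seq: list[str],
    protected: set[int],
    gc_target: float,
    open_starts: Sequence[int],
    rng: np.random.Generator,
) -> None:
    """Nudge unprotected bases toward the GC target without creating ATGs
    or in-frame stops downstream of an open uORF."""
    L = len(seq)
    if L == 0:
        return

    open_frame_floor = {p % 3: p for p in open_starts}

    def safe(pos: int, base: str) -> bool:
        old = seq[pos]
        seq[pos] = base
        try:
            for w in range(max(0, pos - 2), min(L - 2, pos + 1)):
                if seq[w] == "A" and seq[w + 1] == "T" and seq[w + 2] == "G":
                    return False
            for w in range(max(0, pos - 2), min(L - 2, pos + 1)):
                f = w % 3
                if f in open_frame_floor and w >= open_frame_floor[f]:
                    if "".join(seq[w : w + 3]) in STOP_CODONS:
                        return False
            return True
        finally:
            seq[pos] = old

    def gc_count() -> int:
        return sum(1 for b in seq if b in "GC")

    target_count = gc_target / 100.0 * L
    candidates = np.array([i for i in range(L) if i not in protected], dtype=int)
    rng.shuffle(candidates)
    for pos in candidates:
        pos = int(pos)
        diff = gc_count() - target_count
        if abs(diff) <= 0.5:
            break
        if diff < 0 and seq[pos] in "AT":
            seq[pos] = "C"  # C can never complete an ATG or a stop codon
        elif diff > 0 and seq[pos] in "GC":
            for b in ("T", "A"):
                if safe(pos, b):
                    seq[pos] = b
                    break


def simulate_labeled(spec: SimulationSpec) -> pd.DataFrame:
    """Draw labeled feature vectors from the spec's logistic ground truth.

    Covariates: A uniform integer in ``a_range`` (always >= 1), B uniform
    in {0..min(b_max, A)}, C uniform integer in ``c_range``, D uniform in
    ``d_range``; the label is Bernoulli with probability equal to the
    logistic score at the spec's coefficients.  Returns a DataFrame with
    the four feature columns and an integer ``label`` column, indexed by
    synthetic gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    A = rng.integers(spec.a_range[0], spec.a_range[1] + 1, size=spec.n)
    B = np.array([rng.integers(0, min(spec.b_max, a) + 1) for a in A])
    C = rng.integers(spec.c_range[0], spec.c_range[1] + 1, size=spec.n)
    D = rng.uniform(spec.d_range[0], spec.d_range[1], size=spec.n)
    X = np.column_stack([A, B, C, D]).astype(float)
    p = expit(interaction_design(X) @ np.asarray(spec.beta.beta))
    label = (rng.uniform(size=spec.n) < p).astype(int)
    return pd.DataFrame(
        {
            "uorfs": A,
            "atf4like": B,
            "length": C,
            "gc_percent": D,
            "label": label,
        },
        index=pd.Index([f"SYN{i:06d}" for i in range(spec.n)], name="gene_id"),
    )


def simulate_expression_table(
    n: int, boundary_coverage: bool = True, seed: int = 0
) -> pd.DataFrame:
    """RNA-seq/Ribo-seq rows spanning every training-filter region.

    Each row carries an ``expected`` column ('positive', 'negative' or
    'dropped') stating what the training filter should do with it.  With
    ``boundary_coverage`` the table additionally contains rows sitting
    exactly on the +-0.2 and 0.05 boundaries, all expected 'dropped'.
    """
    rng = np.random.default_rng(seed)
    regions = ("pass_pos", "pass_neg", "rna_excluded", "fdr_excluded", "dead_zone")
    rows = []
    for i in range(n):
        region = regions[i % len(regions)]
        rna = rng.uniform(-0.19, 0.19)
        fdr = rng.uniform(0.0, 0.049)
        sign = rng.choice([-1.0, 1.0])
        ribo = sign * rng.uniform(0.25, 3.0)
        expected = "dropped"
        if region == "pass_pos":
            ribo = abs(ribo)
            expected = "positive"
        elif region == "pass_neg":
            ribo = -abs(ribo)
            expected = "negative"
        elif region == "rna_excluded":
            rna = rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 2.0)
        elif region == "fdr_excluded":
            fdr = rng.uniform(0.051, 1.0)
        elif region == "dead_zone":
            ribo = rng.uniform(-0.19, 0.19)
        rows.append((f"GENE{i:06d}", rna, ribo, fdr, expected))
    if boundary_coverage:
        rows += [
            ("BOUND_RNA_HI", 0.2, 1.0, 0.01, "dropped"),
            ("BOUND_RNA_LO", -0.2, -1.0, 0.01, "dropped"),
            ("BOUND_RIBO_HI", 0.0, 0.2, 0.01, "dropped"),
            ("BOUND_RIBO_LO", 0.0, -0.2, 0.01, "dropped"),
            ("BOUND_FDR", 0.0, 1.0, 0.05, "dropped"),
        ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "rnaseq_log2fc", "riboseq_log2fc",
                 "riboseq_fdr", "expected"],
    )


def simulate_te_table(
    n: int, boundary_coverage: bool = True, seed: int = 0
) -> pd.DataFrame:
    """Translation-efficiency rows spanning every testing-filter region.

    TE log2FC is the mutant-vs-wild-type contrast: negative TE change
    marks a transcript whose translation the phosphorylation-competent
    state enhances (expected 'positive').
    """
    rng = np.random.default_rng(seed)
    regions = ("pass_pos", "pass_neg", "padj_excluded", "dead_zone")
    rows = []
    for i in range(n):
        region = regions[i % len(regions)]
        padj = rng.uniform(0.0, 0.049)
        te = rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 3.0)
        expected = "dropped"
        if region == "pass_pos":
            te = -abs(te)
            expected = "positive"
        elif region == "pass_neg":
            te = abs(te)
            expected = "negative"
        elif region == "padj_excluded":
            padj = rng.uniform(0.051, 1.0)
        elif region == "dead_zone":
            te = rng.uniform(-0.2, 0.2)
        rows.append((f"GENE{i:06d}", te, padj, expected))
    if boundary_coverage:
        rows += [
            ("BOUND_TE_LO", -0.2, 0.01, "dropped"),
            ("BOUND_TE_HI", 0.2, 0.01, "dropped"),
            ("BOUND_PADJ", -1.0, 0.05, "dropped"),
        ]
    return pd.DataFrame(
        rows, columns=["gene_id", "te_log2fc", "te_padj", "expected"]
    )


def shared_label_sets(
    n_shared_pos: int,
    n_shared_neg: int,
    n_train_only: int = 50,
    n_test_only: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labeled train/test gene sets sharing a known concordant overlap.

    Builds two labeled tables whose intersection contains exactly
    ``n_shared_pos`` genes labeled positive in both and ``n_shared_neg``
    labeled negative in both, for exercising the train/test
    de-duplication and its concordance statistics.
    """
    rng = np.random.default_rng(seed)
    rows_train, rows_test = [], []
    for i in range(n_shared_pos):
        g = f"SHARED_P{i:04d}"
        rows_train.append((g, "positive"))
        rows_test.append((g, "positive"))
    for i in range(n_shared_neg):
        g = f"SHARED_N{i:04d}"
        rows_train.append((g, "negative"))
        rows_test.append((g, "negative"))
    for i in range(n_train_only):
        rows_train.append((f"TRAIN{i:04d}", rng.choice(["positive", "negative"])))
    for i in range(n_test_only):
        rows_test.append((f"TEST{i:04d}", rng.choice(["positive", "negative"])))
    cols = ["gene_id", "label"]
    return pd.DataFrame(rows_train, columns=cols), pd.DataFrame(rows_test, columns=cols)
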
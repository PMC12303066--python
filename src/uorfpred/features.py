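"""5'UTR feature extraction: uORF scanning and the four model covariates.

The classifier uses four covariates per 5'UTR:

* **A (uorfs)** — number of accepted upstream ORFs.  An AUG is accepted
  when, scanning each reading frame 5'->3' independently, it (i) has an
  adequate Kozak context, (ii) starts at least 30 nt downstream of the
  previously accepted AUG in the same frame (leaky-scanning spacing), and
  (iii) does not lie inside the span of a previously accepted same-frame
  uORF that never reached a stop codon.
* **B (atf4like)** — number of reading frames (0-3) holding an accepted
  uORF that is still open at the end of the 5'UTR and is preceded by at
  least one already-terminated accepted uORF in any frame.  This is the
  delayed-reinitiation architecture of the ATF4 transcript.
* **C (length)** — 5'UTR length in nucleotides.
* **D (gc_percent)** — percentage of G or C over the total length
  (N counts toward the length but never as G/C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import UTRRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Minimum spacing (nt) between accepted AUG starts, allowing the ribosome
#: to resume scanning between uAUGs; AUGs "less than 30 nucleotides apart"
#: from the previously accepted one are excluded.
MIN_UORF_SPACING = 30

KozakMode = Literal["adequate", "strong", "any"]
SpacingScope = Literal["frame", "global"]

FEATURE_COLUMNS = ("uorfs", "atf4like", "length", "gc_percent")


@dataclass(frozen=True)
class UORF:
    """An accepted upstream ORF.

    ``start`` indexes the A of the AUG (0-based); ``frame`` is
    ``start % 3``.  ``terminated`` is true when an in-frame stop codon
    completes within the 5'UTR, in which case ``stop_end`` is the 0-based
    half-open end of that stop codon.  A uORF whose stop codon would lie
    in the CDS is open ("lacking a STOP codon") by construction.
    """

    start: int
    frame: int
    terminated: bool
    stop_end: int | None
    kozak_adequate: bool


@dataclass(frozen=True)
class UTRFeatures:
    """The four covariates A (uorfs), B (atf4like), C (length), D (%GC)."""

    uorfs: int
    atf4like: int
    length: int
    gc_percent: float

    def as_tuple(self) -> tuple[int, int, int, float]:
        return (self.uorfs, self.atf4like, self.length, self.gc_percent)


def kozak_adequate(seq: str, aug_start: int, mode: KozakMode = "adequate") -> bool:
    """Kozak-context test for the AUG starting at ``aug_start``.

    ``adequate``: purine (A/G) at position -3 OR G at +4; ``strong``
    demands both; ``any`` accepts every AUG.  Context positions outside
    the 5'UTR, or holding N, never satisfy the condition.
    """
    if seq[aug_start : aug_start + 3] != "ATG":
        raise ValueError(f"no ATG at position {aug_start}")
    if mode == "any":
        return True
    minus3 = seq[aug_start - 3] in "AG" if aug_start >= 3 else False
    plus4 = seq[aug_start + 3] == "G" if aug_start + 3 < len(seq) else False
    if mode == "strong":
        return minus3 and plus4
    return minus3 or plus4


def _first_stop(seq: str, start: int) -> int | None:
    """Half-open end of the first in-frame stop completing within seq."""
    for i in range(start + 3, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i + 3
    return None


def scan_uorfs(
    seq: str,
    kozak: KozakMode = "adequate",
    spacing_scope: SpacingScope = "frame",
) -> list[UORF]:
    """Scan a normalized 5'UTR for accepted uORFs, sorted by start.

    Each of the three reading frames is scanned 5'->3' independently.
    An ATG is accepted iff it passes the Kozak test, starts >= 30 nt
    downstream of the previously accepted ATG (in the same frame by
    default, or in any frame with ``spacing_scope="global"``), and is not
    inside the span of a previously accepted same-frame uORF that lacks a
    stop codon.  ATG triplets containing N never match.
    """
    n = len(seq)
    if n < 3:
        return []
    atg_positions = [i for i in range(n - 2) if seq[i : i + 3] == "ATG"]
    accepted: list[UORF] = []
    last_accepted_by_frame: dict[int, int] = {}
    open_uorf_by_frame: dict[int, int] = {}  # frame -> start of open uORF
    last_accepted_global = None
    for pos in atg_positions:
        frame = pos % 3
        if not kozak_adequate(seq, pos, mode=kozak):
            continue
        if spacing_scope == "global":
            prev = last_accepted_global
        else:
            prev = last_accepted_by_frame.get(frame)
        if prev is not None and pos - prev < MIN_UORF_SPACING:
            continue
        if frame in open_uorf_by_frame:
            continue  # inside a same-frame uORF that never terminates
        stop_end = _first_stop(seq, pos)
        uorf = UORF(
            start=pos,
            frame=frame,
            terminated=stop_end is not None,
            stop_end=stop_end,
            kozak_adequate=True,
        )
        accepted.append(uorf)
        last_accepted_by_frame[frame] = pos
        last_accepted_global = pos
        if stop_end is None:
            open_uorf_by_frame[frame] = pos
    return accepted


def atf4like(seq: str, uorfs: Sequence[UORF]) -> int:
    """Count frames with an open uORF preceded by a terminated uORF.

    A frame contributes when it holds an accepted uORF with no stop codon
    whose start is at or after the stop-codon end of at least one
    terminated accepted uORF in any frame — the re-initiation geometry of
    ATF4's 5'UTR.
    """
    stop_ends = [u.stop_end for u in uorfs if u.terminated]
    if not stop_ends:
        return 0
    earliest_stop = min(stop_ends)
    frames = {
        u.frame for u in uorfs if not u.terminated and u.start >= earliest_stop
    }
    return len(frames)


def gc_percent(seq: str) -> float:
    """Percent G+C over total length; 0.0 for the empty sequence."""
    if not seq:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def compute_features(
    record: UTRRecord | str,
    kozak: KozakMode = "adequate",
    spacing_scope: SpacingScope = "frame",
) -> UTRFeatures:
    """Compute the four covariates for one 5'UTR (record or raw sequence)."""
    seq = record.sequence if isinstance(record, UTRRecord) else record
    uorfs = scan_uorfs(seq, kozak=kozak, spacing_scope=spacing_scope)
    return UTRFeatures(
        uorfs=len(uorfs),
        atf4like=atf4like(seq, uorfs),
        length=len(seq),
        gc_percent=gc_percent(seq),
    )


class UTRFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform 5'UTR sequences into the model's feature table.

    A stateless scikit-learn transformer: ``transform`` accepts a list of
    :class:`~uorfpred.io.UTRRecord` or raw sequence strings and returns a
    DataFrame with columns ``uorfs``, ``atf4like``, ``length``,
    ``gc_percent`` (plus ``gene_id``/``transcript_id`` when records carry
    them, as the index).

    Parameters
    ----------
    kozak : {"adequate", "strong", "any"}, default "adequate"
        Kozak-context rule for accepting an AUG.
    spacing_scope : {"frame", "global"}, default "frame"
        Whether the 30-nt spacing rule compares against the previously
        accepted AUG in the same frame or in any frame.
    """

    def __init__(
        self,
        kozak: KozakMode = "adequate",
        spacing_scope: SpacingScope = "frame",
    ):
        self.kozak = kozak
        self.spacing_scope = spacing_scope

    def fit(self, X: Iterable[UTRRecord | str], y=None) -> "UTRFeatureExtractor":
        if self.kozak not in ("adequate", "strong", "any"):
            raise ValueError(f"unknown kozak mode {self.kozak!r}")
        if self.spacing_scope not in ("frame", "global"):
            raise ValueError(f"unknown spacing scope {self.spacing_scope!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[UTRRecord | str]) -> pd.DataFrame:
        self.fit(X)
        rows = []
        index = []
        for i, item in enumerate(X):
            f = compute_features(
                item, kozak=self.kozak, spacing_scope=self.spacing_scope
            )
            rows.append(f.as_tuple())
            index.append(item.gene_id if isinstance(item, UTRRecord) else i)
        return pd.DataFrame(
            np.asarray(rows, dtype=float).reshape(-1, 4),
            columns=list(FEATURE_COLUMNS),
            index=pd.Index(index, name="gene_id"),
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_COLUMNS, dtype=object)
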
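"""Sequence I/O and 5'UTR derivation.

The 5'UTR of a transcript is recovered as the 5' portion of the cDNA that
is not part of the coding sequence: the prefix of the cDNA strictly before
the first occurrence of the CDS.  All coordinates are 0-based, half-open;
sequences are sense-strand DNA over {A, C, G, T, N}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class InvalidCharacterError(ValueError):
    """A sequence contains a symbol outside {A, C, G, T, N} (after U->T)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position} "
            "(expected A, C, G, T, U or N)"
        )


class CDSNotFoundError(ValueError):
    """The CDS is not a contiguous substring of the cDNA."""


class MalformedFastaError(ValueError):
    """Sequence data encountered before the first FASTA header."""


class UnknownIdentifierError(KeyError):
    """A stable identifier was not found by the transcript fetcher."""


@dataclass
class UTRRecord:
    """One transcript's 5'UTR with its identifiers.

    Attributes
    ----------
    gene_id : str
        Stable gene identifier; must be non-empty.
    transcript_id : str
        Stable transcript identifier; may be empty.
    sequence : str
        Normalized 5'UTR, 5'->3', over {A, C, G, T, N}; may be empty
        (a transcript whose cDNA starts with its CDS has no 5'UTR).
    """

    gene_id: str
    sequence: str
    transcript_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        self.sequence = normalize_sequence(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase, map RNA U to DNA T, and validate the alphabet.

    Raises
    ------
    InvalidCharacterError
        Naming the first offending symbol and its 1-based position.
    """
    seq = raw.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in _VALID_BASES:
            raise InvalidCharacterError(raw[i], i + 1)
    return seq


def derive_utr(cdna: str, cds: str) -> str:
    """Return the 5'UTR: the cDNA prefix before the first CDS occurrence.

    When the CDS occurs more than once the first (5'-most) occurrence is
    used, yielding the shortest 5'UTR; additional matches are logged.

    Raises
    ------
    ValueError
        If ``cds`` is empty.
    CDSNotFoundError
        If ``cds`` is not a substring of ``cdna``.
    """
    if not cds:
        raise ValueError("cds must be non-empty")
    pos = cdna.find(cds)
    if pos < 0:
        raise CDSNotFoundError("CDS is not a contiguous substring of the cDNA")
    if cdna.find(cds, pos + 1) >= 0:
        logger.info("CDS occurs more than once in cDNA; using first occurrence")
    return cdna[:pos]


def _parse_header(description: str) -> tuple[str, str]:
    # "gene|transcript ..." or "gene transcript ..." or bare "gene"
    head = description.split()[0] if description.split() else ""
    if "|" in head:
        gene_id, _, transcript_id = head.partition("|")
    else:
        gene_id = head
        rest = description.split()
        transcript_id = rest[1] if len(rest) > 1 else ""
    return gene_id, transcript_id


def read_fasta(path: str | Path) -> list[UTRRecord]:
    """Read UTR records from FASTA; sequences are normalized on read.

    The first header token is the gene_id; an optional second token
    (pipe- or whitespace-delimited) is the transcript_id.

    Raises
    ------
    MalformedFastaError
        If sequence data precedes the first ``>`` header.
    """
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise MalformedFastaError(
                    f"{path}: sequence data before first FASTA header"
                )
            break
    records: list[UTRRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, transcript_id = _parse_header(rec.description)
        key = f"{gene_id}|{transcript_id}"
        if key in seen:
            warnings.warn(f"duplicate identifier {key!r} in {path}", stacklevel=2)
        seen.add(key)
        records.append(
            UTRRecord(gene_id=gene_id, transcript_id=transcript_id,
                      sequence=str(rec.seq))
        )
    return records


def write_fasta(records: Iterable[UTRRecord], path: str | Path) -> None:
    """Write UTR records as FASTA, header ``>gene_id|transcript_id``."""
    seq_records = []
    for r in records:
        name = f"{r.gene_id}|{r.transcript_id}" if r.transcript_id else r.gene_id
        seq_records.append(SeqRecord(Seq(r.sequence), id=name, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


# Type of an injectable transcript source: gene_id -> (cdna, cds).
TranscriptFetcher = Callable[[str], tuple[str, str]]


def fetch_transcript(
    gene_id: str, fetcher: TranscriptFetcher | None = None
) -> tuple[str, str]:
    """Return (cDNA, CDS) for a gene's canonical transcript.

    The default backend queries the Ensembl REST API and requires network
    access; tests and offline pipelines inject ``fetcher``.  Raises
    UnknownIdentifierError when the identifier cannot be resolved.
    """
    if fetcher is None:
        fetcher = _ensembl_rest_fetcher
    cdna, cds = fetcher(gene_id)
    return normalize_sequence(cdna), normalize_sequence(cds)


def _ensembl_rest_fetcher(gene_id: str) -> tuple[str, str]:
    """Query Ensembl REST for the canonical transcript's cDNA and CDS."""
    import json
    from urllib.error import HTTPError
    from urllib.request import Request, urlopen

    base = "https://rest.ensembl.org"

    def _get(url: str, content_type: str) -> str:
        req = Request(url, headers={"Content-Type": content_type})
        try:
            with urlopen(req, timeout=30) as resp:
                return resp.read().decode()
        except HTTPError as exc:
            if exc.code == 404:
                raise UnknownIdentifierError(gene_id) from exc
            raise

    lookup = json.loads(
        _get(f"{base}/lookup/id/{gene_id}?expand=1", "application/json")
    )
    canonical = next(
        (t["id"] for t in lookup.get("Transcript", []) if t.get("is_canonical")),
        None,
    )
    if canonical is None:
        raise UnknownIdentifierError(gene_id)
    cdna = _get(f"{base}/sequence/id/{canonical}?type=cdna", "text/x-fasta")
    cds = _get(f"{base}/sequence/id/{canonical}?type=cds", "text/x-fasta")

    def _strip(fasta: str) -> str:
        return "".join(l.strip() for l in fasta.splitlines() if not l.startswith(">"))

    return _strip(cdna), _strip(cds)


def derive_utrs_from_pairs(
    pairs: Sequence[tuple[str, str, str]]
) -> list[UTRRecord]:
    """Derive 5'UTRs from (gene_id, cdna, cds) triples.

    Triples whose CDS is not found verbatim in the cDNA (edge annotation
    artifacts) are skipped with a log line rather than aborting the batch.
    """
    out: list[UTRRecord] = []
    for gene_id, cdna, cds in pairs:
        try:
            utr = derive_utr(normalize_sequence(cdna), normalize_sequence(cds))
        except CDSNotFoundError:
            logger.warning("%s: CDS not found in cDNA; skipped", gene_id)
            continue
        out.append(UTRRecord(gene_id=gene_id, sequence=utr))
    return out
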
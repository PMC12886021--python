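"""UMI-deduplicated miRNA quantification from small-RNA reads.

Read layout (QIAseq-style small-RNA libraries): the miRNA insert sits at the
5' end, followed by the 3' adapter, followed by a 12-bp unique molecular
identifier (UMI).  Only read 1 of a pair is used — mature miRNAs (18-25 nt)
are fully covered by a single read.  The processing rules are:

1. find the first exact adapter occurrence; the bases before it are the
   insert, the ``umi_length`` bases after it are the UMI;
2. keep inserts of length >= 20 (reads exceeding 19 bp);
3. assign the insert to the unique reference miRNA whose full sequence is an
   exact prefix of the insert (no mismatches, no reverse-complement
   matching) — unambiguous when the reference is prefix-free;
4. count distinct UMIs per miRNA (exact-match deduplication), collapsing PCR
   duplicates to molecules;
5. keep samples whose total deduplicated count exceeds 10^4.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd
import pysam

from .simulate import MiRNAReference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadLayout:
    adapter: str
    umi_length: int = 12
    min_insert_length: int = 20

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.min_insert_length < 1:
            raise ValueError("min_insert_length must be >= 1")


class Extraction(NamedTuple):
    insert: str | None
    umi: str | None
    reject_reason: str | None  # None | no_adapter | short_insert | short_umi

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


def extract_insert_umi(read_sequence: str, layout: ReadLayout) -> Extraction:
    """Split a read into (insert, UMI) at the first exact adapter match.

    Rejection is a value (``reject_reason``), never an exception.
    """
    pos = read_sequence.find(layout.adapter)
    if pos < 0:
        return Extraction(None, None, "no_adapter")
    insert = read_sequence[:pos]
    if len(insert) < layout.min_insert_length:
        return Extraction(None, None, "short_insert")
    umi_start = pos + len(layout.adapter)
    umi = read_sequence[umi_start: umi_start + layout.umi_length]
    if len(umi) < layout.umi_length:
        return Extraction(None, None, "short_umi")
    return Extraction(insert, umi, None)


class _PrefixIndex:
    """Exact-prefix lookup: maps an insert to the reference entry whose full
    sequence is a prefix of the insert."""

    def __init__(self, ref: MiRNAReference):
        self.seq_to_id = ref.seq_to_id()
        lengths = {len(s) for s in self.seq_to_id}
        self.lengths = sorted(lengths)
        if not ref.is_prefix_free():
            logger.warning("reference is not prefix-free; ambiguous inserts "
                           "will be counted as unassigned")

    def assign(self, insert: str) -> str | None:
        hits = [self.seq_to_id[insert[:L]]
                for L in self.lengths
                if L <= len(insert) and insert[:L] in self.seq_to_id]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            logger.warning("ambiguous insert matches %d references; "
                           "counted as unassigned", len(hits))
        return None


def assign_mirna(insert: str, ref: MiRNAReference) -> str | None:
    """Assign an insert to a reference miRNA by exact full-length prefix match.

    Reverse complements are never considered.  Returns ``None`` when no (or
    more than one) reference matches.
    """
    return _PrefixIndex(ref).assign(insert)


def deduplicate_umis(assignments: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Collapse (miRNA id, UMI) pairs to molecule counts.

    ``count[m]`` = number of distinct UMIs observed with miRNA ``m``;
    order-invariant by construction.
    """
    seen: dict[str, set[str]] = {}
    for mirna_id, umi in assignments:
        seen.setdefault(mirna_id, set()).add(umi)
    return {m: len(umis) for m, umis in seen.items()}


def _iter_reads(reads):
    """Yield (name, sequence) from a FASTQ path (optionally gzipped) or an
    in-memory iterable of (name, sequence) pairs."""
    if isinstance(reads, (str, os.PathLike)):
        try:
            with pysam.FastxFile(str(reads)) as fh:
                for i, rec in enumerate(fh):
                    if rec.sequence is None:
                        raise ValueError(f"malformed FASTQ record at index {i}")
                    yield rec.name, rec.sequence.upper()
        except OSError as exc:
            raise ValueError(f"cannot parse FASTQ {reads}: {exc}") from exc
    else:
        for name, seq in reads:
            yield name, seq.upper()


def quantify_sample(reads, ref: MiRNAReference, layout: ReadLayout):
    """Run the full read-to-counts pipeline for one sample.

    ``reads`` is a FASTQ path (plain or .gz) or an iterable of
    ``(name, sequence)`` pairs.  Returns ``(counts, qc)``: a Series over all
    reference ids (zeros included) and a QC dict with ``n_reads``,
    ``n_adapter``, ``n_assigned``, ``total_counts`` and ``species_detected``
    (miRNAs with >= 2 deduplicated counts).
    """
    index = _PrefixIndex(ref)
    n_reads = n_adapter = n_assigned = 0
    assignments: list[tuple[str, str]] = []
    for _, seq in _iter_reads(reads):
        n_reads += 1
        ext = extract_insert_umi(seq, layout)
        if ext.reject_reason == "no_adapter":
            continue
        n_adapter += 1
        if not ext.accepted:
            continue
        mirna_id = index.assign(ext.insert)
        if mirna_id is None:
            continue
        n_assigned += 1
        assignments.append((mirna_id, ext.umi))
    dedup = deduplicate_umis(assignments)
    counts = pd.Series(0, index=ref.ids, dtype=int, name="count")
    for m, c in dedup.items():
        counts[m] = c
    qc = {
        "n_reads": n_reads,
        "n_adapter": n_adapter,
        "n_assigned": n_assigned,
        "total_counts": int(counts.sum()),
        "species_detected": int((counts >= 2).sum()),
    }
    return counts, qc


def species_detected(counts: pd.DataFrame, min_count: int = 2) -> pd.Series:
    """Distinct miRNAs detected with >= ``min_count`` counts, per sample."""
    return (counts >= min_count).sum(axis=0)


def qc_filter_samples(counts: pd.DataFrame, min_total: int = 10_000):
    """Keep samples whose total count strictly exceeds ``min_total``.

    Returns ``(kept, dropped_ids)``; the comparison is strict ('more than').
    """
    totals = counts.sum(axis=0)
    keep = totals > min_total
    dropped = list(totals.index[~keep])
    return counts.loc[:, keep], dropped
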
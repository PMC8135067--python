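"""PCR-duplicate removal and read cleaning for single-end FASTQ libraries.

Two reads are called PCR duplicates when their first 10 bases are identical
and the whole reads are more than 90% similar. Duplicate clusters are the
single-linkage closure of that pairwise relation; the first-seen read of each
cluster is kept as its representative. Adapter trimming and mean-quality
filtering are provided as configurable contract-level cleaning steps (the
underlying criteria are not fixed by the duplicate rule itself).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError

PREFIX_LEN = 10
SIMILARITY_MIN = 0.90
VALID_BASES = frozenset("ACGTN")


@dataclass
class ReadRecord:
    """One sequencing read: id, bases (A/C/G/T/N) and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != len(self.qualities):
            raise InvalidInputError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InvalidInputError(
                f"read {self.read_id!r}: invalid bases {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


@dataclass
class DedupReport:
    """Accounting of a deduplication run.

    ``clusters`` lists, for every cluster with at least one removed read,
    the kept representative and the ids removed in its favour.
    """

    n_input: int
    n_kept: int
    n_removed_duplicates: int
    clusters: list[tuple[str, list[str]]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_kept": self.n_kept,
                "n_removed_duplicates": self.n_removed_duplicates,
                "clusters": [
                    {"kept": kept, "removed": removed}
                    for kept, removed in self.clusters
                ],
            },
            indent=2,
        )


# -- pairwise rule ----------------------------------------------------------

_aligner = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def similarity(a: ReadRecord, b: ReadRecord) -> float:
    """Whole-read identity fraction in [0, 1].

    Equal-length reads use positional identity (Hamming matches / L).
    Unequal lengths fall back to global alignment with match +1 and
    mismatch/gap 0; identity is matches over the alignment length.
    Symmetric by construction.
    """
    if not a.sequence or not b.sequence:
        raise InvalidInputError("similarity undefined for empty sequences")
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a.sequence, b.sequence))
        return matches / len(a)
    aln = _aligner.align(a.sequence, b.sequence)[0]
    return aln.score / aln.length


def is_pcr_duplicate(a: ReadRecord, b: ReadRecord) -> bool:
    """Apply the duplicate rule: identical first 10 bases AND similarity > 0.90.

    The prefix comparison is case-insensitive and an N never matches, not
    even another N. Both inequalities in the similarity clause are strict.
    """
    if len(a) < PREFIX_LEN or len(b) < PREFIX_LEN:
        raise InvalidInputError(
            f"duplicate test requires reads of >= {PREFIX_LEN} nt"
        )
    pa, pb = a.sequence[:PREFIX_LEN], b.sequence[:PREFIX_LEN]
    if "N" in pa or "N" in pb or pa != pb:
        return False
    return similarity(a, b) > SIMILARITY_MIN


# -- clustering -------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # keep the lower (earlier-seen) index as root
            if ri > rj:
                ri, rj = rj, ri
            self.parent[rj] = ri


def deduplicate(reads: Sequence[ReadRecord]) -> tuple[list[ReadRecord], DedupReport]:
    """Remove PCR duplicates, keeping the first-seen read of each cluster.

    Reads are bucketed by their exact 10-mer prefix (a prefix containing an
    N can match nothing, so such reads are always kept); within a bucket the
    pairwise rule is applied with single-linkage closure.
    """
    reads = list(reads)
    uf = _UnionFind(len(reads))
    buckets: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        if len(r) < PREFIX_LEN:
            raise InvalidInputError(
                f"read {r.read_id!r} shorter than {PREFIX_LEN} nt"
            )
        prefix = r.sequence[:PREFIX_LEN]
        if "N" in prefix:
            continue
        buckets.setdefault(prefix, []).append(i)
    for members in buckets.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if uf.find(i) == uf.find(j):
                    continue
                if is_pcr_duplicate(reads[i], reads[j]):
                    uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(reads)):
        clusters.setdefault(uf.find(i), []).append(i)
    kept: list[ReadRecord] = []
    cluster_report: list[tuple[str, list[str]]] = []
    for root in sorted(clusters):
        members = sorted(clusters[root])
        rep = reads[members[0]]
        kept.append(rep)
        if len(members) > 1:
            cluster_report.append(
                (rep.read_id, [reads[m].read_id for m in members[1:]])
            )
    report = DedupReport(
        n_input=len(reads),
        n_kept=len(kept),
        n_removed_duplicates=len(reads) - len(kept),
        clusters=cluster_report,
    )
    return kept, report


def cluster_partition(reads: Sequence[ReadRecord]) -> list[frozenset[str]]:
    """The duplicate-cluster partition as a set of read-id groups."""
    kept, report = deduplicate(reads)
    removed = {rid for _, ids in report.clusters for rid in ids}
    multi = {kept_id: frozenset([kept_id, *ids]) for kept_id, ids in report.clusters}
    parts = [
        multi.get(r.read_id, frozenset([r.read_id]))
        for r in kept
    ]
    assert sum(len(p) for p in parts) == len(reads), (removed, parts)
    return parts


# -- adapter / quality cleaning ---------------------------------------------


def filter_adapters_and_quality(
    reads: Iterable[ReadRecord],
    adapter: str | None = None,
    min_mean_q: float = 20.0,
    min_overlap: int = 5,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Trim 3' adapter matches and drop low-mean-quality reads.

    A read is trimmed when its 3' end equals a prefix of ``adapter`` of at
    least ``min_overlap`` bases (longest such match wins). Reads whose mean
    Phred score is below ``min_mean_q`` are removed after trimming. These
    criteria are package defaults, configurable because no single standard
    exists for them.
    """
    if adapter is not None and not adapter:
        raise InvalidInputError("adapter must be non-empty when provided")
    adapter = adapter.upper() if adapter else None
    kept: list[ReadRecord] = []
    n_trimmed = n_removed = 0
    for r in reads:
        if adapter:
            for k in range(len(adapter), min_overlap - 1, -1):
                if r.sequence.endswith(adapter[:k]):
                    r = ReadRecord(r.read_id, r.sequence[:-k], list(r.qualities[:-k]))
                    n_trimmed += 1
                    break
        if r.mean_quality < min_mean_q:
            n_removed += 1
            continue
        kept.append(r)
    return kept, {
        "n_trimmed": n_trimmed,
        "n_removed_low_quality": n_removed,
        "n_kept": len(kept),
    }


# -- FASTQ I/O ---------------------------------------------------------------


def read_fastq(path) -> list[ReadRecord]:
    return [
        ReadRecord(
            rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
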
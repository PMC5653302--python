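"""From per-sample reads to a filtered, depth-normalized OTU table.

The clustering step reproduces abundance-greedy 16S OTU building at 95%
similarity: sequences are processed in decreasing global abundance and each
either joins the first centroid it matches at or above the threshold or
founds a new OTU.  Identity is computed on homopolymer-collapsed sequences
(pyrosequencing's dominant error mode is homopolymer length), as matching
columns over alignment columns of a global edit-distance alignment (edlib).

Post-processing removes OTUs that are global singletons consisting of a
single dereplication singleton, then normalizes every sample to a fixed
read depth by random subsampling without replacement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReadSet",
    "OTUTable",
    "collapse_homopolymers",
    "sequence_identity",
    "cluster_otus",
    "filter_singletons",
    "rarefy",
    "richness",
    "richness_and_curves",
]

_VALID_RE = re.compile(r"^[ACGT]+$")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DEFAULT_SIMILARITY = 0.95
DEFAULT_DEPTH = 10_000


# ---------------------------------------------------------------------------
# Read sets
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Dereplicated reads of one sample: unique sequences with counts."""

    sample_id: str
    sequences: list
    abundances: np.ndarray
    n_rejected: int = 0

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=int)
        if (self.abundances < 1).any():
            raise ValueError("dereplicated abundances must be >= 1")

    @property
    def total_reads(self) -> int:
        return int(self.abundances.sum())

    @classmethod
    def from_sequences(cls, sample_id: str, reads: Iterable[str]) -> "ReadSet":
        """Dereplicate raw reads; non-ACGT reads are rejected (and counted)."""
        counts: dict[str, int] = {}
        rejected = 0
        for r in reads:
            r = str(r).upper()
            if not _VALID_RE.match(r):
                rejected += 1
                continue
            counts[r] = counts.get(r, 0) + 1
        if rejected:
            logger.warning("%s: rejected %d non-ACGT reads", sample_id, rejected)
        if not counts:
            raise ValueError(f"sample {sample_id!r} has no valid reads")
        seqs = sorted(counts)
        return cls(
            sample_id=sample_id,
            sequences=seqs,
            abundances=np.array([counts[s] for s in seqs]),
            n_rejected=rejected,
        )

    @classmethod
    def from_fasta(cls, path, sample_id: str | None = None) -> "ReadSet":
        import gzip
        from Bio import SeqIO

        path = str(path)
        if sample_id is None:
            sample_id = re.sub(r"\.(fa|fasta)(\.gz)?$", "", path.rsplit("/", 1)[-1])
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            reads = [str(rec.seq) for rec in SeqIO.parse(fh, "fasta")]
        return cls.from_sequences(sample_id, reads)


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

def collapse_homopolymers(seq: str) -> str:
    """Collapse every run of an identical base to length 1."""
    return re.sub(r"(.)\1+", r"\1", seq)


def sequence_identity(a: str, b: str) -> float:
    """Alignment identity of two sequences, homopolymer-insensitive.

    Both sequences are homopolymer-collapsed, globally aligned with unit
    edit costs, and identity = matching columns / alignment columns (a gap
    occupies one column).
    """
    ca, cb = collapse_homopolymers(a), collapse_homopolymers(b)
    if ca == cb:
        return 1.0
    if cb < ca:            # canonical order makes the identity symmetric
        ca, cb = cb, ca
    res = edlib.align(ca, cb, mode="NW", task="path")
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (cols - res["editDistance"]) / cols


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

@dataclass
class OTUTable:
    """Sample x OTU contingency table with filtering/normalization provenance.

    ``counts`` has samples in rows and OTUs in columns.  ``provenance`` maps
    each OTU id to its total count, number of member sequences, and whether
    its single read was a dereplication singleton (used by the strict
    singleton filter).
    """

    counts: pd.DataFrame
    clustered_at: float = DEFAULT_SIMILARITY
    singleton_filtered: bool = False
    normalized_depth: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be nonnegative")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.counts.sum(axis=0) > 0
        return OTUTable(
            counts=self.counts.loc[:, keep],
            clustered_at=self.clustered_at,
            singleton_filtered=self.singleton_filtered,
            normalized_depth=self.normalized_depth,
            provenance={k: v for k, v in self.provenance.items() if keep.get(k, False)},
        )

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "OTUTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=counts.astype(int), **kwargs)


# ---------------------------------------------------------------------------
# Greedy clustering
# ---------------------------------------------------------------------------

def cluster_otus(
    readsets: Sequence[ReadSet],
    threshold: float = DEFAULT_SIMILARITY,
) -> OTUTable:
    """Abundance-greedy clustering of all samples' reads into OTUs.

    Unique sequences are ordered by decreasing global (summed over samples)
    abundance, ties broken lexicographically.  Each sequence joins the first
    existing centroid — in founding order — whose identity is at or above
    ``threshold``, else founds a new OTU.  Deterministic: permuting the
    input sample order does not change the partition.
    """
    if not readsets:
        raise ValueError("empty read collection")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")

    global_abund: dict[str, int] = {}
    per_sample: dict[str, dict[str, int]] = {}
    for rs in readsets:
        d = per_sample.setdefault(rs.sample_id, {})
        for seq, a in zip(rs.sequences, rs.abundances):
            d[seq] = d.get(seq, 0) + int(a)
            global_abund[seq] = global_abund.get(seq, 0) + int(a)
    order = sorted(global_abund, key=lambda s: (-global_abund[s], s))

    centroids: list[str] = []
    assignment: dict[str, int] = {}
    for seq in order:
        placed = False
        for k, cen in enumerate(centroids):
            if sequence_identity(seq, cen) >= threshold:
                assignment[seq] = k
                placed = True
                break
        if not placed:
            assignment[seq] = len(centroids)
            centroids.append(seq)

    sample_ids = list(per_sample)
    otu_ids = [f"OTU{k + 1}" for k in range(len(centroids))]
    mat = np.zeros((len(sample_ids), len(centroids)), dtype=int)
    members: dict[int, list] = {k: [] for k in range(len(centroids))}
    for i, sid in enumerate(sample_ids):
        for seq, a in per_sample[sid].items():
            mat[i, assignment[seq]] += a
    for seq in order:
        members[assignment[seq]].append(seq)

    provenance = {}
    for k, oid in enumerate(otu_ids):
        total = int(mat[:, k].sum())
        mem = members[k]
        provenance[oid] = {
            "centroid": centroids[k],
            "total": total,
            "n_members": len(mem),
            "single_derep_singleton": total == 1 and len(mem) == 1
            and global_abund[mem[0]] == 1,
        }
    return OTUTable(
        counts=pd.DataFrame(mat, index=sample_ids, columns=otu_ids),
        clustered_at=threshold,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Singleton filtering
# ---------------------------------------------------------------------------

def filter_singletons(table: OTUTable) -> tuple[OTUTable, pd.DataFrame]:
    """Remove single-singleton OTUs from the table.

    Strict rule: drop an OTU only if its total count over all samples is 1
    *and* that single read was a dereplication singleton (an unclustered
    one-off read).  Without provenance the filter falls back to the
    total-count-1 rule with a logged warning.  Returns the filtered table
    and a per-sample report of removed OTUs and reads.
    """
    if table.singleton_filtered:
        raise ValueError("table already singleton-filtered")
    totals = table.counts.sum(axis=0)
    if table.provenance:
        drop = [
            oid
            for oid in table.otu_ids
            if totals[oid] == 1 and table.provenance[oid]["single_derep_singleton"]
        ]
    else:
        logger.warning(
            "no clustering provenance: falling back to the total-count-1 rule"
        )
        drop = [oid for oid in table.otu_ids if totals[oid] == 1]
    dropped = table.counts[drop]
    report = pd.DataFrame(
        {
            "removed_otus": (dropped > 0).sum(axis=1),
            "removed_reads": dropped.sum(axis=1),
        }
    )
    filtered = OTUTable(
        counts=table.counts.drop(columns=drop),
        clustered_at=table.clustered_at,
        singleton_filtered=True,
        normalized_depth=table.normalized_depth,
        provenance={k: v for k, v in table.provenance.items() if k not in drop},
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Depth normalization (rarefaction)
# ---------------------------------------------------------------------------

def rarefy(table: OTUTable, depth: int = DEFAULT_DEPTH, seed=None) -> OTUTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (logged).  The draw
    is multivariate hypergeometric per sample, reproducible for a fixed
    seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError("all samples below depth")
    if (~keep).any():
        logger.info(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            int((~keep).sum()), depth, list(table.counts.index[~keep]),
        )
    sub = table.counts.loc[keep]
    out = np.empty(sub.shape, dtype=int)
    for i in range(sub.shape[0]):
        row = sub.iloc[i].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OTUTable(
        counts=pd.DataFrame(out, index=sub.index, columns=sub.columns),
        clustered_at=table.clustered_at,
        singleton_filtered=table.singleton_filtered,
        normalized_depth=depth,
        provenance=table.provenance,
    ).drop_empty_otus()


# ---------------------------------------------------------------------------
# Richness and curves
# ---------------------------------------------------------------------------

def richness(table: OTUTable) -> pd.Series:
    """Per-sample OTU richness: count of OTUs with a nonzero count."""
    if table.counts.empty:
        raise ValueError("empty table")
    return (table.counts > 0).sum(axis=1).rename("richness")


def richness_and_curves(
    table: OTUTable,
    depths: Sequence[int] | None = None,
    reps: int = 10,
    seed=None,
    n_orderings: int = 1000,
):
    """Richness vector, per-sample rarefaction curves, accumulation curve.

    Rarefaction: mean subsampled richness at each depth over ``reps``
    hypergeometric draws (depths above a sample's total are skipped).
    Accumulation: mean cumulative number of distinct OTUs over
    ``n_orderings`` random orderings of the samples.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rich = richness(table)
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=1)
    if depths is None:
        depths = np.unique(np.linspace(1, totals.max(), 12).astype(int))

    rar = {}
    for i, sid in enumerate(table.sample_ids):
        row = counts[i]
        vals = []
        for d in depths:
            if d > totals[i]:
                vals.append(np.nan)
            elif d == totals[i]:
                vals.append(float((row > 0).sum()))
            else:
                r = [
                    (rng.multivariate_hypergeometric(row, int(d)) > 0).sum()
                    for _ in range(reps)
                ]
                vals.append(float(np.mean(r)))
        rar[sid] = vals
    rarefaction = pd.DataFrame(rar, index=pd.Index(depths, name="depth"))

    n = counts.shape[0]
    present = counts > 0
    acc = np.zeros(n)
    for _ in range(n_orderings):
        perm = rng.permutation(n)
        seen = np.zeros(counts.shape[1], dtype=bool)
        for j, s in enumerate(perm):
            seen |= present[s]
            acc[j] += seen.sum()
    accumulation = pd.Series(
        acc / n_orderings,
        index=pd.RangeIndex(1, n + 1, name="n_samples"),
        name="mean_distinct_otus",
    )
    return rich, rarefaction, accumulation
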
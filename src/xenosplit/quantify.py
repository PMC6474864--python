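"""Gene-level read counting by transcript k-mer pseudo-alignment.

Synthetic transcripts carry no introns, so spliced genome alignment is
unnecessary: a read pair is assigned to the gene whose transcript contains
the largest number of the pair's canonical k-mers, with ties and zero-hit
reads left unassigned (unique-assignment counting, integral counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .xenoclassify import encode_seq, kmers_of_sequence

META_COLUMNS = ("patient_id", "tissue", "pipeline", "passage")

#: sentinel gene ids in the k-mer -> gene lookup
UNASSIGNED = -1
_SHARED = -2


# --------------------------------------------------------------------------
# Count matrix container
# --------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample metadata.

    ``meta`` is indexed by sample id and carries ``patient_id``,
    ``tissue`` (donor/pdx), ``pipeline`` (patient/pdx) and optionally
    ``passage``.
    """

    counts: np.ndarray
    genes: list[str]
    samples: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        missing = set(self.samples) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from meta: {sorted(missing)}")
        self.meta = self.meta.loc[self.samples]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def cpm(self, library_sizes: np.ndarray | None = None) -> np.ndarray:
        lib = self.library_sizes if library_sizes is None else library_sizes
        if np.any(lib <= 0):
            bad = [self.samples[i] for i in np.flatnonzero(lib <= 0)]
            raise ValueError(f"zero library size for samples: {bad}")
        return self.counts / lib * 1e6

    def subset_genes(self, keep) -> "CountMatrix":
        """Subset by boolean mask or iterable of gene ids (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            keep = set(keep)
            mask = np.array([g in keep for g in self.genes])
        genes = [g for g, m in zip(self.genes, mask) if m]
        return CountMatrix(self.counts[mask], genes, list(self.samples), self.meta)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountMatrix(
            self.counts[:, idx], list(self.genes), list(sample_ids), self.meta
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def to_tsv(self, counts_path, samples_path=None) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            meta = self.meta.copy()
            meta.index.name = "sample_id"
            meta.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(dtype=np.int64),
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            meta,
        )


def make_meta(records: dict[str, dict]) -> pd.DataFrame:
    """Build a sample metadata frame from ``{sample_id: fields}``."""
    meta = pd.DataFrame.from_dict(records, orient="index")
    meta.index.name = "sample_id"
    return meta


# --------------------------------------------------------------------------
# Gene k-mer map and read assignment
# --------------------------------------------------------------------------


@dataclass
class GeneKmerMap:
    """Canonical k-mer -> gene lookup built from the graft transcriptome.

    k-mers occurring in more than one gene are kept (they score every gene
    containing them) but routed through a sparse side table.
    """

    k: int
    codes: np.ndarray  # sorted unique uint64
    owners: np.ndarray  # int32 gene index, _SHARED for multi-gene k-mers
    shared: dict = field(default_factory=dict)  # code -> tuple of gene indexes
    gene_ids: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def build_gene_kmer_map(genes, k: int = 25) -> GeneKmerMap:
    """Index the graft transcripts for assignment.

    ``genes`` is a sequence of objects with ``gene_id``/``graft_seq``
    attributes, or of ``(gene_id, sequence)`` tuples.
    """
    from .xenoclassify import _validate_k

    _validate_k(k)
    gene_ids: list[str] = []
    code_parts: list[np.ndarray] = []
    owner_parts: list[np.ndarray] = []
    for gi, g in enumerate(genes):
        if isinstance(g, tuple):
            gid, seq = g
        else:
            gid, seq = g.gene_id, g.graft_seq
        gene_ids.append(gid)
        km = np.unique(kmers_of_sequence(encode_seq(seq), k))
        code_parts.append(km)
        owner_parts.append(np.full(km.shape[0], gi, dtype=np.int32))
    codes = np.concatenate(code_parts)
    owners = np.concatenate(owner_parts)
    order = np.argsort(codes, kind="stable")
    codes, owners = codes[order], owners[order]
    # collapse runs of equal codes; multi-owner codes go to the side table
    boundary = np.ones(codes.shape[0], dtype=bool)
    boundary[1:] = codes[1:] != codes[:-1]
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], codes.shape[0])
    uniq = codes[starts]
    uniq_owner = owners[starts].copy()
    shared: dict = {}
    multi = np.flatnonzero((ends - starts) > 1)
    for i in multi:
        uniq_owner[i] = _SHARED
        shared[int(uniq[i])] = tuple(
            int(o) for o in np.unique(owners[starts[i] : ends[i]])
        )
    return GeneKmerMap(k=k, codes=uniq, owners=uniq_owner, shared=shared, gene_ids=gene_ids)


def _lookup_owners(gmap: GeneKmerMap, kmers: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Gene index per k-mer (UNASSIGNED where absent or invalid)."""
    out = np.full(kmers.shape, UNASSIGNED, dtype=np.int32)
    if gmap.codes.size:
        pos = np.searchsorted(gmap.codes, kmers)
        pos[pos == gmap.codes.size] = gmap.codes.size - 1
        hit = (gmap.codes[pos] == kmers) & valid
        out[hit] = gmap.owners[pos[hit]]
    return out


def _argmax_run(ids: np.ndarray) -> np.ndarray:
    """Unique-mode gene per row of an owner-id matrix (ties/empty -> -1).

    Fast path: rows whose valid ids are all equal (the overwhelmingly common
    case — a fragment's k-mers come from one transcript) are assigned
    directly; the remainder fall back to a sort/run-length scan where the
    gene with the longest run wins if that length is uniquely attained.
    """
    n_total = ids.shape[0]
    big = np.where(ids >= 0, ids, np.iinfo(np.int32).max)
    lo = big.min(axis=1)
    hi = ids.max(axis=1)
    out = np.full(n_total, UNASSIGNED, dtype=np.int32)
    single = lo == hi  # exactly one distinct valid id
    out[single] = hi[single]
    out[hi < 0] = UNASSIGNED  # no valid id at all
    rest = np.flatnonzero(~single & (hi >= 0))
    if rest.size:
        out[rest] = _argmax_run_slow(ids[rest])
    return out


def _argmax_run_slow(ids: np.ndarray) -> np.ndarray:
    n, m = ids.shape
    s = np.sort(ids, axis=1)
    idx = np.arange(m)
    change = np.ones((n, m), dtype=bool)
    change[:, 1:] = s[:, 1:] != s[:, :-1]
    start = np.where(change, idx, 0)
    start = np.maximum.accumulate(start, axis=1)
    nxt = np.where(change, idx, m)
    nxt = np.concatenate([nxt[:, 1:], np.full((n, 1), m)], axis=1)
    nxt = np.minimum.accumulate(nxt[:, ::-1], axis=1)[:, ::-1]
    run_len = nxt - start
    run_len = np.where(s >= 0, run_len, 0)
    best = run_len.max(axis=1)
    best_pos = run_len.argmax(axis=1)
    winner = s[np.arange(n), best_pos]
    # tie: another distinct gene attains the same run length
    tie = np.any(
        (run_len == best[:, None]) & (s != winner[:, None]) & (s >= 0), axis=1
    )
    winner[(best == 0) | tie] = UNASSIGNED
    return winner


def assign_kmers(gmap: GeneKmerMap, km: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Assign read pairs to gene indexes from pre-computed pooled k-mers."""
    if _kernels.HAVE_NUMBA and km.size > 4096:
        assigned, needs_slow = _kernels.assign_single_owner(
            gmap.codes, gmap.owners, np.ascontiguousarray(km), np.ascontiguousarray(valid)
        )
        rows = np.flatnonzero(needs_slow)
        if rows.size:
            assigned[rows] = _assign_kmers_numpy(gmap, km[rows], valid[rows])
        return assigned
    return _assign_kmers_numpy(gmap, km, valid)


def _assign_kmers_numpy(gmap: GeneKmerMap, km: np.ndarray, valid: np.ndarray) -> np.ndarray:
    owners = _lookup_owners(gmap, km, valid)
    has_shared = np.any(owners == _SHARED, axis=1)
    assigned = _argmax_run(np.where(owners == _SHARED, UNASSIGNED, owners))
    if np.any(has_shared):
        for r in np.flatnonzero(has_shared):
            assigned[r] = _assign_with_shared(gmap, km[r], owners[r])
    return assigned


def assign_batch(
    gmap: GeneKmerMap,
    mate1: np.ndarray,
    mate2: np.ndarray | None = None,
) -> np.ndarray:
    """Assign encoded read pairs to gene indexes (-1 = unassigned)."""
    from .xenoclassify import pair_kmers

    km, valid = pair_kmers(mate1, mate2, gmap.k)
    return assign_kmers(gmap, km, valid)


def _assign_with_shared(gmap: GeneKmerMap, kmers: np.ndarray, owners: np.ndarray) -> int:
    scores: dict[int, int] = {}
    for code, owner in zip(kmers, owners):
        if owner == UNASSIGNED:
            continue
        targets = gmap.shared[int(code)] if owner == _SHARED else (int(owner),)
        for t in targets:
            scores[t] = scores.get(t, 0) + 1
    if not scores:
        return UNASSIGNED
    top = max(scores.values())
    winners = [g for g, s in scores.items() if s == top]
    return winners[0] if len(winners) == 1 else UNASSIGNED


def assign_read(pair, gene_kmer_map: GeneKmerMap) -> str | None:
    """Assign one read pair; returns the gene id or None (unassigned)."""
    if isinstance(pair, str):
        s1, s2 = pair, None
    elif isinstance(pair, tuple):
        _, s1, s2 = pair
    else:
        s1, s2 = pair.mate1_seq, pair.mate2_seq
    m1 = encode_seq(s1)[None, :]
    m2 = encode_seq(s2)[None, :] if s2 is not None else None
    gi = assign_batch(gene_kmer_map, m1, m2)[0]
    return None if gi == UNASSIGNED else gene_kmer_map.gene_ids[gi]


def count_sample(
    gmap: GeneKmerMap,
    mate1: np.ndarray,
    mate2: np.ndarray | None = None,
    retained_mask: np.ndarray | None = None,
    kmers: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, int]:
    """Count assignable reads per gene for one sample.

    ``kmers`` may carry pre-computed pooled (codes, valid) from
    classification to avoid recomputing them.  Returns
    ``(count_vector, n_unassigned)``; assigned + unassigned equals the
    number of input (retained) reads.
    """
    if kmers is None:
        if retained_mask is not None:
            mate1 = mate1[retained_mask]
            mate2 = mate2[retained_mask] if mate2 is not None else None
        if mate1.shape[0] == 0:
            return np.zeros(gmap.n_genes, dtype=np.int64), 0
        from .xenoclassify import pair_kmers

        km, valid = pair_kmers(mate1, mate2, gmap.k)
    else:
        km, valid = kmers
        if retained_mask is not None:
            km, valid = km[retained_mask], valid[retained_mask]
        if km.shape[0] == 0:
            return np.zeros(gmap.n_genes, dtype=np.int64), 0
    assigned = assign_kmers(gmap, km, valid)
    ok = assigned >= 0
    vec = np.bincount(assigned[ok], minlength=gmap.n_genes).astype(np.int64)
    return vec, int((~ok).sum())
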
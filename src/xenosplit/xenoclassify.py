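"""k-mer classification of paired-end reads into graft (human) and host (mouse).

Xenograft RNA-seq mixes transcripts of the engrafted human tumor with
transcripts of the murine stroma that infiltrates it.  Before any human
expression analysis, each read pair has to be attributed to one species.
This module does that with the classic dual-reference k-mer partition: every
canonical k-mer of the two transcript references belongs to exactly one of
``graft_only``, ``host_only`` or ``both``, and a read pair is categorised by
which of those sets its k-mers hit.

Categories (``h``/``m``/``b``/``u`` = read k-mers found only-in-graft,
only-in-host, in-both, in-neither):

=========== =====================================
graft       h > 0 and m = 0
host        m > 0 and h = 0
both        h = m = 0 and b > 0
neither     h = m = b = 0
ambiguous   h > 0 and m > 0
=========== =====================================

The "human" portion of a xenograft sample keeps ``graft``, ``ambiguous`` and
``both``; ``host`` and ``neither`` are discarded.  These category semantics
are a clean-room definition consistent with the category names of k-mer
classifiers such as Xenome; no attempt is made to reproduce any particular
tool's probabilistic refinements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _kernels

logger = logging.getLogger("xenosplit")

# --------------------------------------------------------------------------
# 2-bit base encoding
# --------------------------------------------------------------------------

#: A,C,G,T -> 0,1,2,3; anything else -> 255 (invalidates spanning k-mers).
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
    BASE_CODES[ord(chr(_b).lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

INDEX_FORMAT_VERSION = 1

CATEGORIES = ("graft", "host", "both", "neither", "ambiguous")
#: categories selected as the "human" portion of a xenograft sample
RETAINED_CATEGORIES = ("graft", "ambiguous", "both")

CAT_GRAFT, CAT_HOST, CAT_BOTH, CAT_NEITHER, CAT_AMBIGUOUS = range(5)
_RETAINED_CODES = np.array([CAT_GRAFT, CAT_AMBIGUOUS, CAT_BOTH])


def _validate_k(k: int) -> None:
    """k must be odd (strand-unambiguous canonical form) and pack into 64 bits."""
    if k % 2 == 0 or not 3 <= k <= 31:
        raise ValueError(f"k must be odd and in [3, 31], got {k}")


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (255 for non-ACGT letters)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_CODES[raw]


def decode_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def _revcomp_codes(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed 2-bit k-mer codes (vectorised)."""
    out = np.zeros_like(kmers)
    fwd = kmers.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (fwd & np.uint64(3)))
        fwd = fwd >> np.uint64(2)
    return out


def canonical(kmers: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) form: min(k-mer, reverse complement)."""
    return np.minimum(kmers, _revcomp_codes(kmers, k))


def _pack_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-window of a (possibly invalid-containing) code vector."""
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    shifts = np.arange(2 * (k - 1), -1, -2, dtype=np.uint64)
    safe = np.where(win == 255, 0, win)
    return (safe.astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)


def kmers_of_sequence(codes: np.ndarray, k: int) -> np.ndarray:
    """All canonical k-mer codes of one encoded sequence.

    Windows containing a non-ACGT code are skipped (their count is returned
    implicitly by the caller comparing lengths).
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~np.any(win == 255, axis=1)
    fwd = _pack_windows(codes, k)
    # revcomp of window j = forward pack of the complemented, reversed
    # sequence at the mirrored position
    comp = np.where(codes == 255, 255, 3 - codes)[::-1]
    rc = _pack_windows(comp, k)[::-1]
    return np.minimum(fwd, rc)[valid]


def kmers_of_reads(rows: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mers of a batch of equal-length encoded reads.

    Parameters
    ----------
    rows
        (n_reads, read_length) uint8 base-code matrix.

    Returns
    -------
    kmers
        (n_reads, read_length - k + 1) uint64 canonical codes.
    valid
        Same-shape boolean mask; False where the window spans a non-ACGT base.
    """
    n, length = rows.shape
    if length < k:
        raise ValueError(f"read length {length} shorter than k={k}")
    if _kernels.HAVE_NUMBA and rows.size > 4096:
        return _kernels.rolling_canonical_kmers(np.ascontiguousarray(rows), k)
    nwin = length - k + 1
    bad = rows == 255
    safe = np.where(bad, 0, rows).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    out = np.zeros((n, nwin), dtype=np.uint64)
    v = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        v = (v << np.uint64(2)) | safe[:, j]
    out[:, 0] = v
    for j in range(1, nwin):
        v = ((v << np.uint64(2)) & mask) | safe[:, j + k - 1]
        out[:, j] = v
    # reverse complement by the same recurrence run right-to-left on the
    # complemented row (revcomp of window j = pack of complement reversed)
    comp = np.uint64(3) - safe
    rc = np.zeros((n, nwin), dtype=np.uint64)
    v = np.zeros(n, dtype=np.uint64)
    for j in range(length - 1, length - 1 - k, -1):
        v = (v << np.uint64(2)) | comp[:, j]
    rc[:, nwin - 1] = v
    for j in range(nwin - 2, -1, -1):
        v = ((v << np.uint64(2)) & mask) | comp[:, j]
        rc[:, j] = v
    np.minimum(out, rc, out=out)
    # window invalid if it contains any bad base
    cum = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(bad, axis=1, out=cum[:, 1:])
    valid = (cum[:, k:] - cum[:, :-k]) == 0
    return out, valid


# --------------------------------------------------------------------------
# Index
# --------------------------------------------------------------------------


@dataclass
class KmerIndex:
    """Partition of the two references' canonical k-mers.

    The three sorted arrays are pairwise disjoint and together contain every
    canonical k-mer occurring in either reference.
    """

    k: int
    graft_only: np.ndarray
    host_only: np.ndarray
    both_sets: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_k(self.k)

    def _table(self) -> tuple[np.ndarray, np.ndarray]:
        """Merged sorted code table with labels 0=graft, 1=host, 2=both."""
        cached = getattr(self, "_table_cache", None)
        if cached is None:
            codes = np.concatenate([self.graft_only, self.host_only, self.both_sets])
            labels = np.concatenate(
                [
                    np.zeros(self.graft_only.size, np.uint8),
                    np.ones(self.host_only.size, np.uint8),
                    np.full(self.both_sets.size, 2, np.uint8),
                ]
            )
            order = np.argsort(codes)
            cached = (codes[order], labels[order])
            self._table_cache = cached
        return cached

    def membership_counts(
        self, kmers: np.ndarray, valid: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-read (h, m, b, u) counts for a (n_reads, n_windows) k-mer batch."""
        codes, labels = self._table()
        if _kernels.HAVE_NUMBA and kmers.size > 4096:
            return _kernels.classify_counts(
                codes, labels, np.ascontiguousarray(kmers), np.ascontiguousarray(valid)
            )
        lab = np.full(kmers.shape, 3, dtype=np.uint8)  # 3 = absent
        if codes.size:
            pos = np.searchsorted(codes, kmers)
            pos[pos == codes.size] = codes.size - 1
            hit = (codes[pos] == kmers) & valid
            lab[hit] = labels[pos[hit]]
        lab[~valid] = 4  # excluded entirely
        h = (lab == 0).sum(axis=1, dtype=np.int32)
        m = (lab == 1).sum(axis=1, dtype=np.int32)
        b = (lab == 2).sum(axis=1, dtype=np.int32)
        u = (lab == 3).sum(axis=1, dtype=np.int32)
        return h, m, b, u

    def save(self, path) -> None:
        """Serialise to a single ``.npz`` artifact (versioned header field)."""
        header = (
            f"#xenosplit-kmer-index v{INDEX_FORMAT_VERSION} k={self.k}"
        )
        np.savez(
            path,
            header=np.array(header),
            version=np.array([INDEX_FORMAT_VERSION]),
            k=np.array([self.k]),
            graft_only=self.graft_only,
            host_only=self.host_only,
            both_sets=self.both_sets,
            provenance=np.array(repr(self.provenance)),
        )

    @classmethod
    def load(cls, path) -> "KmerIndex":
        import ast

        with np.load(path, allow_pickle=False) as z:
            version = int(z["version"][0])
            if version != INDEX_FORMAT_VERSION:
                raise ValueError(f"unsupported index format version {version}")
            return cls(
                k=int(z["k"][0]),
                graft_only=z["graft_only"],
                host_only=z["host_only"],
                both_sets=z["both_sets"],
                provenance=ast.literal_eval(str(z["provenance"])),
            )


def _collect_reference_kmers(seqs: Iterable[str], k: int) -> np.ndarray:
    parts = []
    skipped = 0
    for seq in seqs:
        codes = encode_seq(seq)
        if codes.shape[0] < k:
            raise ValueError(
                f"k={k} exceeds a reference sequence of length {codes.shape[0]}"
            )
        km = kmers_of_sequence(codes, k)
        skipped += (codes.shape[0] - k + 1) - km.shape[0]
        parts.append(km)
    if skipped:
        logger.info("skipped %d k-mers spanning non-ACGT letters", skipped)
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)


def build_index(
    graft_fasta,
    host_fasta,
    k: int = 25,
) -> KmerIndex:
    """Build the graft/host/both canonical k-mer partition.

    ``graft_fasta`` / ``host_fasta`` may be FASTA file paths or in-memory
    sequences (any iterable of DNA strings).
    """
    graft_seqs, graft_src = _as_sequences(graft_fasta)
    host_seqs, host_src = _as_sequences(host_fasta)
    if not graft_seqs or not host_seqs:
        raise ValueError("both references must contain at least one sequence")
    graft = _collect_reference_kmers(graft_seqs, k)
    host = _collect_reference_kmers(host_seqs, k)
    both = np.intersect1d(graft, host, assume_unique=True)
    graft_only = np.setdiff1d(graft, both, assume_unique=True)
    host_only = np.setdiff1d(host, both, assume_unique=True)
    return KmerIndex(
        k=k,
        graft_only=graft_only,
        host_only=host_only,
        both_sets=both,
        provenance={"graft": graft_src, "host": host_src, "k": k},
    )


def _as_sequences(src) -> tuple[list[str], str]:
    if isinstance(src, (str, bytes)) or hasattr(src, "read"):
        from Bio import SeqIO

        seqs = [str(rec.seq) for rec in SeqIO.parse(src, "fasta")]
        return seqs, str(src)
    return [str(s) for s in src], "<in-memory>"


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


@dataclass
class ReadClassification:
    """Category and k-mer evidence for one read pair."""

    read_id: str
    category: str
    counts: tuple[int, int, int, int]  # (h, m, b, u)


@dataclass
class ClassificationResult:
    """Vectorised classification of a read batch."""

    read_ids: list[str] | None
    category_codes: np.ndarray  # uint8, indexes into CATEGORIES
    h: np.ndarray
    m: np.ndarray
    b: np.ndarray
    u: np.ndarray

    @property
    def categories(self) -> np.ndarray:
        return np.array(CATEGORIES, dtype=object)[self.category_codes]

    def tallies(self) -> dict[str, int]:
        counts = np.bincount(self.category_codes, minlength=5)
        return {cat: int(counts[i]) for i, cat in enumerate(CATEGORIES)}

    def retained_mask(self) -> np.ndarray:
        return np.isin(self.category_codes, _RETAINED_CODES)


def _categorise(h: np.ndarray, m: np.ndarray, b: np.ndarray) -> np.ndarray:
    codes = np.full(h.shape, CAT_NEITHER, dtype=np.uint8)
    codes[(h > 0) & (m == 0)] = CAT_GRAFT
    codes[(m > 0) & (h == 0)] = CAT_HOST
    codes[(h == 0) & (m == 0) & (b > 0)] = CAT_BOTH
    codes[(h > 0) & (m > 0)] = CAT_AMBIGUOUS
    return codes


def pair_kmers(
    mate1: np.ndarray, mate2: np.ndarray | None, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled canonical k-mers (and validity mask) of encoded read pairs."""
    if mate1.shape[1] < k:
        raise ValueError(f"mate length {mate1.shape[1]} shorter than k={k}")
    km1, v1 = kmers_of_reads(mate1, k)
    if mate2 is None:
        return km1, v1
    if mate2.shape[1] < k:
        raise ValueError(f"mate length {mate2.shape[1]} shorter than k={k}")
    km2, v2 = kmers_of_reads(mate2, k)
    return np.concatenate([km1, km2], axis=1), np.concatenate([v1, v2], axis=1)


def classify_kmers(
    index: KmerIndex,
    km: np.ndarray,
    valid: np.ndarray,
    read_ids: Sequence[str] | None = None,
) -> ClassificationResult:
    """Classify pre-computed pooled k-mers of read pairs."""
    h, m, b, u = index.membership_counts(km, valid)
    codes = _categorise(h, m, b)
    return ClassificationResult(
        read_ids=list(read_ids) if read_ids is not None else None,
        category_codes=codes,
        h=h,
        m=m,
        b=b,
        u=u,
    )


def classify_batch(
    index: KmerIndex,
    mate1: np.ndarray,
    mate2: np.ndarray | None = None,
    read_ids: Sequence[str] | None = None,
) -> ClassificationResult:
    """Classify encoded read pairs (``mate1``/``mate2``: (n, L) uint8).

    Both mates are pooled: the (h, m, b, u) counts run over the canonical
    k-mers of the pair, one per position.
    """
    km, valid = pair_kmers(mate1, mate2, index.k)
    h, m, b, u = index.membership_counts(km, valid)
    codes = _categorise(h, m, b)
    return ClassificationResult(
        read_ids=list(read_ids) if read_ids is not None else None,
        category_codes=codes,
        h=h,
        m=m,
        b=b,
        u=u,
    )


def classify_read(pair, index: KmerIndex) -> ReadClassification:
    """Classify a single read pair.

    ``pair`` may be a :class:`~xenosplit.synthetic_data.ReadRecord`, a
    ``(read_id, mate1, mate2)`` tuple, or a plain DNA string (single mate).
    """
    if isinstance(pair, str):
        read_id, s1, s2 = "read", pair, None
    elif isinstance(pair, tuple):
        read_id, s1, s2 = pair
    else:
        read_id, s1, s2 = pair.read_id, pair.mate1_seq, pair.mate2_seq
    for mate in (s1, s2):
        if mate is not None and len(mate) < index.k:
            raise ValueError(
                f"read {read_id!r}: mate shorter than k={index.k}"
            )
    m1 = encode_seq(s1)[None, :]
    m2 = encode_seq(s2)[None, :] if s2 is not None else None
    res = classify_batch(index, m1, m2, read_ids=[read_id])
    return ReadClassification(
        read_id=read_id,
        category=CATEGORIES[res.category_codes[0]],
        counts=(int(res.h[0]), int(res.m[0]), int(res.b[0]), int(res.u[0])),
    )


def select_human(classifications) -> tuple[set, dict]:
    """Reads retained as the "human" portion: graft, ambiguous or both.

    Accepts a :class:`ClassificationResult` or an iterable of
    :class:`ReadClassification`.  Returns ``(read_id_set, report)`` where the
    report carries per-category tallies and fractions.
    """
    if isinstance(classifications, ClassificationResult):
        tallies = classifications.tallies()
        mask = classifications.retained_mask()
        if classifications.read_ids is not None:
            ids = {
                rid
                for rid, keep in zip(classifications.read_ids, mask)
                if keep
            }
        else:
            ids = set(np.flatnonzero(mask))
    else:
        items = list(classifications)
        tallies = {cat: 0 for cat in CATEGORIES}
        ids = set()
        for c in items:
            tallies[c.category] += 1
            if c.category in RETAINED_CATEGORIES:
                ids.add(c.read_id)
    total = sum(tallies.values())
    report = {
        "tallies": tallies,
        "total": total,
        "retained": len(ids),
        "fractions": {
            cat: (n / total if total else 0.0) for cat, n in tallies.items()
        },
    }
    return ids, report
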
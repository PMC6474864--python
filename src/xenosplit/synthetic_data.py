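"""Synthetic dual-species xenograft RNA-seq with known ground truth.

The generator emulates the statistical structure of a paired donor/PDX
ovarian-tumor cohort: nine patients, each contributing a donor tumor
(human carcinoma plus human stroma) and a PDX tumor in which the human
stroma has been replaced by mouse stroma; 51 x 2 paired-end reads; per-gene
human-mouse sequence conservation ranging from low to near-identical; and
negative-binomial count noise with a patient-shared expression factor that
makes members of a pair correlated.

Everything is seeded and deterministic: identical seeds give byte-identical
FASTA/FASTQ/TSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import CountMatrix, make_meta
from .xenoclassify import encode_seq, decode_seq

COMPARTMENTS = ("tumor", "stroma", "shared")

#: default per-gene conservation distribution: Beta(5, 2) spans the low to
#: near-identical range of human-mouse transcript identity.
DEFAULT_CONSERVATION = ("beta", 5.0, 2.0)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePair:
    """A graft gene with its host ortholog and simulation ground truth.

    ``conservation`` is the expected per-base identity between the two
    sequences; ``compartment`` says which tissue compartment expresses the
    gene; ``baseline_mean`` is the expected count at reference library size;
    ``dispersion`` is the negative-binomial dispersion phi
    (var = mu + phi * mu^2).
    """

    gene_id: str
    graft_seq: str
    host_seq: str
    conservation: float
    compartment: str
    baseline_mean: float
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if len(self.graft_seq) != len(self.host_seq):
            raise ValueError(f"{self.gene_id}: sequence lengths differ")
        if not 0.0 <= self.conservation <= 1.0:
            raise ValueError(f"{self.gene_id}: conservation outside [0, 1]")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.gene_id}: unknown compartment {self.compartment!r}")
        if not (self.baseline_mean >= 0 and math.isfinite(self.baseline_mean)):
            raise ValueError(f"{self.gene_id}: invalid baseline_mean")
        if self.dispersion <= 0:
            raise ValueError(f"{self.gene_id}: dispersion must be positive")

    @property
    def length(self) -> int:
        return len(self.graft_seq)

    def identity(self) -> float:
        """Empirical per-base identity between graft and host sequence."""
        a = np.frombuffer(self.graft_seq.encode(), dtype=np.uint8)
        b = np.frombuffer(self.host_seq.encode(), dtype=np.uint8)
        return float((a == b).mean())


@dataclass(frozen=True)
class ReadRecord:
    """One (possibly simulated) read pair with optional true origin."""

    read_id: str
    mate1_seq: str
    mate2_seq: str | None
    true_species: str = "unknown"  # graft | host | unknown
    true_gene: str = "unknown"
    sample_id: str = ""


@dataclass
class CohortDesign:
    """Study design knobs for the simulated donor/PDX cohort.

    Defaults emulate the modeled cohort: nine donor/PDX pairs sequenced as
    51 x 2 paired-end reads, with ~16% of PDX reads of mouse origin.  The
    donor stromal fragment fraction (0.3) is a free parameter.
    """

    n_pairs: int = 9
    read_length: int = 51
    fragments_per_sample: int = 200_000
    stroma_fraction_donor: float = 0.3
    mouse_stroma_fraction_pdx: float = 0.16
    fragment_length: int = 200
    base_error_rate: float = 0.001
    patient_sigma: float = 0.3
    passages: Sequence[int] | None = None
    seed: int = 0

    def validate(self, genes: Sequence[GenePair] | None = None) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name in ("stroma_fraction_donor", "mouse_stroma_fraction_pdx", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fragment_length < 2 * self.read_length:
            raise ValueError("fragment_length must be >= 2 * read_length")
        if self.passages is not None and len(self.passages) != self.n_pairs:
            raise ValueError("passages must have one entry per pair")
        if genes is not None:
            shortest = min(g.length for g in genes)
            if self.fragment_length > shortest:
                raise ValueError(
                    f"fragment_length {self.fragment_length} exceeds shortest "
                    f"transcript ({shortest} nt)"
                )
            if self.read_length > shortest:
                raise ValueError("read_length exceeds shortest transcript")

    def pdx_passages(self) -> list[int]:
        if self.passages is not None:
            return list(self.passages)
        # deterministic 1..5 cycle; distinct values for passage association
        return [(i % 5) + 1 for i in range(self.n_pairs)]


def donor_sample_id(i: int) -> str:
    return f"P{i + 1:02d}_donor"


def pdx_sample_id(i: int) -> str:
    return f"P{i + 1:02d}_pdx"


# --------------------------------------------------------------------------
# Gene pairs
# --------------------------------------------------------------------------


def _draw_conservation(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec is None:
        spec = DEFAULT_CONSERVATION
    if callable(spec):
        values = np.asarray(spec(n, rng), dtype=float)
    elif hasattr(spec, "rvs"):
        values = np.asarray(spec.rvs(size=n, random_state=rng), dtype=float)
    elif isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "beta":
        values = rng.beta(spec[1], spec[2], size=n)
    else:
        values = np.asarray(spec, dtype=float)
        if values.shape != (n,):
            raise ValueError("conservation array must have one value per gene")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("conservation values must lie in [0, 1]")
    return values


def simulate_gene_pairs(
    n_genes: int,
    conservation_distribution=None,
    stroma_proportion: float = 0.3,
    seed: int = 0,
    length_range: tuple[int, int] = (300, 3000),
    baseline_log_mean: float = math.log(60.0),
    baseline_sigma: float = 1.0,
    dispersion: float = 0.1,
) -> list[GenePair]:
    """Simulate orthologous graft/host gene pairs with a conservation gradient.

    The host sequence differs from the graft sequence by
    ``round((1 - conservation) * length)`` substitutions at uniformly drawn
    positions, each substituted uniformly among the three other bases, so the
    empirical identity matches the requested conservation to within 1/length.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0.0 <= stroma_proportion <= 1.0:
        raise ValueError("stroma_proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    conservation = _draw_conservation(conservation_distribution, n_genes, rng)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_genes)
    n_stroma = int(stroma_proportion * n_genes)
    stroma_idx = set(rng.choice(n_genes, size=n_stroma, replace=False).tolist())
    baselines = rng.lognormal(baseline_log_mean, baseline_sigma, size=n_genes)
    genes: list[GenePair] = []
    for i in range(n_genes):
        length = int(lengths[i])
        graft = rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)
        host = graft.copy()
        n_sub = int(round((1.0 - conservation[i]) * length))
        if n_sub > 0:
            pos = rng.choice(length, size=n_sub, replace=False)
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            host[pos] = (host[pos] + shift) % 4
        genes.append(
            GenePair(
                gene_id=f"G{i:05d}",
                graft_seq=decode_seq(graft),
                host_seq=decode_seq(host),
                conservation=float(conservation[i]),
                compartment="stroma" if i in stroma_idx else "tumor",
                baseline_mean=float(baselines[i]),
                dispersion=dispersion,
            )
        )
    return genes


# --------------------------------------------------------------------------
# Counts
# --------------------------------------------------------------------------


def _compartment_weights(genes: Sequence[GenePair], design: CohortDesign) -> np.ndarray:
    """Per-gene expression weight of the stromal compartment in donor tissue.

    Stroma baselines are scaled so the expected stromal share of donor
    fragments equals ``stroma_fraction_donor``.
    """
    mu = np.array([g.baseline_mean for g in genes])
    stroma = np.array([g.compartment == "stroma" for g in genes])
    w = np.ones(len(genes))
    f = design.stroma_fraction_donor
    if stroma.any() and mu[stroma].sum() > 0:
        if f == 0.0:
            w[stroma] = 0.0
        else:
            w[stroma] = f / (1.0 - f) * mu[~stroma].sum() / mu[stroma].sum()
    return w


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, phi) with var = mean + phi * mean^2 (Poisson at phi -> 0)."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    tiny = phi < 1e-8
    pp = pos & ~tiny
    if pp.any():
        size = 1.0 / phi[pp]
        p = size / (size + mean[pp])
        out[pp] = rng.negative_binomial(size, p)
    pt = pos & tiny
    if pt.any():
        out[pt] = rng.poisson(mean[pt])
    return out


def expected_counts(
    genes: Sequence[GenePair], design: CohortDesign
) -> tuple[np.ndarray, np.ndarray]:
    """(donor, pdx) expected human-origin counts per gene, before patient effects."""
    mu = np.array([g.baseline_mean for g in genes])
    stroma = np.array([g.compartment == "stroma" for g in genes])
    w = _compartment_weights(genes, design)
    donor = mu * np.where(stroma, w, 1.0)
    pdx = mu * np.where(stroma, 0.0, 1.0)
    return donor, pdx


def simulate_counts(genes: Sequence[GenePair], design: CohortDesign) -> CountMatrix:
    """Ground-truth human expression counts for the donor/PDX cohort.

    Donor samples express tumor plus (human) stroma compartments; the PDX
    human fraction expresses the tumor compartment only.  A per-gene,
    per-patient lognormal factor (sigma ``patient_sigma``) is shared between
    the two members of a pair, making pairs correlated.
    """
    design.validate()
    for g in genes:
        if g.dispersion <= 0:
            raise ValueError(f"{g.gene_id}: non-positive dispersion")
    rng = np.random.default_rng(design.seed)
    donor_mu, pdx_mu = expected_counts(genes, design)
    phi = np.array([g.dispersion for g in genes])
    n_genes, n_pairs = len(genes), design.n_pairs
    patient_factor = rng.lognormal(0.0, design.patient_sigma, size=(n_genes, n_pairs))
    passages = design.pdx_passages()
    samples: list[str] = []
    meta_records: dict[str, dict] = {}
    cols: list[np.ndarray] = []
    for i in range(n_pairs):
        pid = f"P{i + 1:02d}"
        for sid, mu_vec, tissue, pipeline, passage in (
            (donor_sample_id(i), donor_mu, "donor", "patient", None),
            (pdx_sample_id(i), pdx_mu, "pdx", "pdx", passages[i]),
        ):
            samples.append(sid)
            meta_records[sid] = {
                "patient_id": pid,
                "tissue": tissue,
                "pipeline": pipeline,
                "passage": passage,
            }
            cols.append(_nb_draw(rng, mu_vec * patient_factor[:, i], phi))
    counts = np.stack(cols, axis=1)
    return CountMatrix(counts, [g.gene_id for g in genes], samples, make_meta(meta_records))


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------


@dataclass
class SampleReads:
    """Encoded read pairs of one sample plus per-read simulation truth."""

    sample_id: str
    mate1: np.ndarray  # (n, read_length) uint8 base codes
    mate2: np.ndarray
    true_species: np.ndarray  # uint8: 0 = graft, 1 = host
    true_gene: np.ndarray  # int32 gene index

    @property
    def n_reads(self) -> int:
        return self.mate1.shape[0]

    def read_ids(self) -> list[str]:
        return [f"{self.sample_id}:{i}" for i in range(self.n_reads)]

    def records(self, genes: Sequence[GenePair]) -> list[ReadRecord]:
        return [
            ReadRecord(
                read_id=f"{self.sample_id}:{i}",
                mate1_seq=decode_seq(self.mate1[i]),
                mate2_seq=decode_seq(self.mate2[i]),
                true_species="graft" if self.true_species[i] == 0 else "host",
                true_gene=genes[self.true_gene[i]].gene_id,
                sample_id=self.sample_id,
            )
            for i in range(self.n_reads)
        ]


def _concat_transcripts(genes: Sequence[GenePair], attr: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    seqs = [encode_seq(getattr(g, attr)) for g in genes]
    lengths = np.array([s.shape[0] for s in seqs])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return np.concatenate(seqs), offsets, lengths


def _apply_errors(mate: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    mask = rng.random(mate.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        mate[mask] = (mate[mask] + shift) % 4


def _fragments_to_reads(
    big: np.ndarray,
    offsets: np.ndarray,
    lengths: np.ndarray,
    gene_idx: np.ndarray,
    design: CohortDesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    L, F = design.read_length, design.fragment_length
    max_start = lengths[gene_idx] - F
    start = offsets[gene_idx] + np.floor(
        rng.random(gene_idx.shape[0]) * (max_start + 1)
    ).astype(np.int64)
    idx = np.arange(L)
    mate1 = big[start[:, None] + idx]
    # mate2: reverse complement of the fragment's last L bases
    tail = big[(start + F - L)[:, None] + idx]
    mate2 = (3 - tail[:, ::-1]).astype(np.uint8)
    _apply_errors(mate1, design.base_error_rate, rng)
    _apply_errors(mate2, design.base_error_rate, rng)
    return mate1, mate2


def simulate_sample_reads(
    genes: Sequence[GenePair],
    design: CohortDesign,
    human_counts: CountMatrix,
    sample_id: str,
    rng: np.random.Generator,
    graft_ref: tuple | None = None,
    host_ref: tuple | None = None,
) -> SampleReads:
    """Simulate one sample's read pairs.

    Donor samples contain graft-origin fragments only; PDX samples mix
    graft-origin fragments (tumor compartment) with host-origin fragments
    (host orthologs of stroma genes) at ``mouse_stroma_fraction_pdx``.
    Fragment start positions are uniform along the transcript.
    """
    design.validate(genes)
    graft_ref = graft_ref or _concat_transcripts(genes, "graft_seq")
    col = human_counts.samples.index(sample_id)
    tissue = human_counts.meta.loc[sample_id, "tissue"]
    weights = human_counts.counts[:, col].astype(float)
    n_frag = design.fragments_per_sample
    if tissue == "pdx" and design.mouse_stroma_fraction_pdx > 0:
        host_ref = host_ref or _concat_transcripts(genes, "host_seq")
        n_host = int(rng.binomial(n_frag, design.mouse_stroma_fraction_pdx))
    else:
        n_host = 0
    n_graft = n_frag - n_host

    if weights.sum() <= 0 and n_graft > 0:
        raise ValueError(f"{sample_id}: no human expression to sample reads from")
    graft_gene = np.repeat(
        np.arange(len(genes)),
        rng.multinomial(n_graft, weights / weights.sum()) if n_graft else np.zeros(len(genes), int),
    ).astype(np.int64)
    m1g, m2g = _fragments_to_reads(*graft_ref, graft_gene, design, rng)

    if n_host:
        donor_mu, _ = expected_counts(genes, design)
        stroma = np.array([g.compartment == "stroma" for g in genes])
        hw = np.where(stroma, donor_mu, 0.0)
        if hw.sum() <= 0:
            raise ValueError("mouse_stroma_fraction_pdx > 0 but no stroma genes")
        host_gene = np.repeat(
            np.arange(len(genes)), rng.multinomial(n_host, hw / hw.sum())
        ).astype(np.int64)
        m1h, m2h = _fragments_to_reads(*host_ref, host_gene, design, rng)
        mate1 = np.concatenate([m1g, m1h])
        mate2 = np.concatenate([m2g, m2h])
        species = np.concatenate(
            [np.zeros(n_graft, np.uint8), np.ones(n_host, np.uint8)]
        )
        gene_idx = np.concatenate([graft_gene, host_gene]).astype(np.int32)
    else:
        mate1, mate2 = m1g, m2g
        species = np.zeros(n_graft, np.uint8)
        gene_idx = graft_gene.astype(np.int32)
    return SampleReads(sample_id, mate1, mate2, species, gene_idx)


def simulate_reads(
    genes: Sequence[GenePair],
    design: CohortDesign,
    human_counts: CountMatrix,
    samples: Sequence[str] | None = None,
):
    """Yield :class:`SampleReads` for each sample of the cohort (seeded).

    Per-sample RNG streams are spawned from ``design.seed`` so any subset of
    samples reproduces byte-identically.
    """
    design.validate(genes)
    graft_ref = _concat_transcripts(genes, "graft_seq")
    host_ref = _concat_transcripts(genes, "host_seq")
    sample_list = list(samples) if samples is not None else list(human_counts.samples)
    root = np.random.SeedSequence(design.seed)
    streams = dict(zip(human_counts.samples, root.spawn(len(human_counts.samples))))
    for sid in sample_list:
        rng = np.random.default_rng(streams[sid])
        yield simulate_sample_reads(
            genes, design, human_counts, sid, rng, graft_ref, host_ref
        )


# --------------------------------------------------------------------------
# Micro-dissected stroma/epithelium emulation
# --------------------------------------------------------------------------


def simulate_microdissected(
    genes: Sequence[GenePair],
    n_per_group: int = 10,
    contamination: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Counts emulating laser micro-dissected tumor-epithelium (TE) and
    tumor-associated stroma (TS) profiles from an independent cohort.

    TE samples express tumor-compartment genes (stroma genes only at the
    cross-contamination floor) and vice versa, so the TE-vs-TS differential
    list is enriched for the same stromal genes that separate donor and PDX
    tumors.
    """
    rng = np.random.default_rng(seed)
    mu = np.array([g.baseline_mean for g in genes])
    phi = np.array([g.dispersion for g in genes])
    stroma = np.array([g.compartment == "stroma" for g in genes])
    te_mu = mu * np.where(stroma, contamination, 1.0)
    ts_mu = mu * np.where(stroma, 1.0, contamination)
    samples, cols, meta_records = [], [], {}
    for grp, grp_mu in (("epithelium", te_mu), ("stroma", ts_mu)):
        for j in range(n_per_group):
            sid = f"{'TE' if grp == 'epithelium' else 'TS'}{j + 1:02d}"
            subj = rng.lognormal(0.0, 0.2, size=len(genes))
            samples.append(sid)
            meta_records[sid] = {
                "patient_id": sid,
                "tissue": grp,
                "pipeline": "microarray",
                "passage": None,
            }
            cols.append(_nb_draw(rng, grp_mu * subj, phi))
    counts = np.stack(cols, axis=1)
    return CountMatrix(counts, [g.gene_id for g in genes], samples, make_meta(meta_records))


# --------------------------------------------------------------------------
# File output
# --------------------------------------------------------------------------


def write_fasta(genes: Sequence[GenePair], graft_path, host_path) -> None:
    for path, attr in ((graft_path, "graft_seq"), (host_path, "host_seq")):
        with open(path, "w") as fh:
            for g in genes:
                fh.write(f">{g.gene_id}\n{getattr(g, attr)}\n")


def write_fastq(reads: SampleReads, r1_path, r2_path, quality_char: str = "I") -> None:
    qual = quality_char * reads.mate1.shape[1]
    for path, mates in ((r1_path, reads.mate1), (r2_path, reads.mate2)):
        with open(path, "w") as fh:
            for i in range(reads.n_reads):
                fh.write(
                    f"@{reads.sample_id}:{i}\n{decode_seq(mates[i])}\n+\n{qual}\n"
                )


def read_fastq_pair(r1_path, r2_path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a paired FASTQ into encoded mate matrices (equal-length reads)."""
    from Bio import SeqIO

    ids, m1, m2 = [], [], []
    for rec1, rec2 in zip(SeqIO.parse(r1_path, "fastq"), SeqIO.parse(r2_path, "fastq")):
        ids.append(rec1.id)
        m1.append(encode_seq(str(rec1.seq)))
        m2.append(encode_seq(str(rec2.seq)))
    return np.stack(m1), np.stack(m2), ids


def write_truth_genes(genes: Sequence[GenePair], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "compartment": [g.compartment for g in genes],
            "conservation": [g.conservation for g in genes],
            "baseline_mean": [g.baseline_mean for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_truth_reads(reads: SampleReads, genes: Sequence[GenePair], path, append: bool = False) -> None:
    with open(path, "a" if append else "w") as fh:
        if not append:
            fh.write("read_id\tsample_id\ttrue_species\ttrue_gene\n")
        species = np.where(reads.true_species == 0, "graft", "host")
        for i in range(reads.n_reads):
            fh.write(
                f"{reads.sample_id}:{i}\t{reads.sample_id}\t{species[i]}\t"
                f"{genes[reads.true_gene[i]].gene_id}\n"
            )
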
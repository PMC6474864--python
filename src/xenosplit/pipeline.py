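"""End-to-end workflows separating graft and host signal in xenograft RNA-seq.

Two workflows are orchestrated on top of the simulation, classification,
quantification and testing modules:

A. **Pipeline-sensitivity control.** The donor (never-xenografted) samples
   are processed twice — through the *patient* pipeline (every read
   quantified) and through the *PDX* pipeline (classify, keep the "human"
   portion, quantify).  Paired differential expression between the two
   processings of the same samples flags genes whose measurement is an
   artifact of read classification; those genes are excluded downstream and
   their conservation compared against the background.

B. **Donor-vs-PDX differential workflow.**  Donor samples run the patient
   pipeline, PDX samples the PDX pipeline; artifact genes are removed after
   the expression filter; patient-paired NB testing yields the donor-PDX
   differential genes (XDGs); concordance (pair correlations, clustering,
   passage association) is reported before and after XDG exclusion; and the
   XDG list is tested for overlap with a stroma-vs-epithelium differential
   list derived from synthetic micro-dissected profiles.

Every run writes a JSON manifest (versions, seed, parameters, input hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    cluster_alignment,
    correlation_before_after,
    donor_pdx_pairs,
    log_cpm,
    passage_association,
)
from .conservation import compare_flagged_vs_background, conservation_from_genes
from .enrichment import hypergeom_overlap
from .paired_de import (
    call_degs,
    filter_low_expression,
    nb_test,
    paired_nb_test,
    unpaired_nb_test,
)
from .quantify import (
    CountMatrix,
    GeneKmerMap,
    build_gene_kmer_map,
    count_sample,
    make_meta,
)
from .synthetic_data import (
    CohortDesign,
    GenePair,
    SampleReads,
    simulate_counts,
    simulate_gene_pairs,
    simulate_microdissected,
    simulate_reads,
)
from .xenoclassify import (
    ClassificationResult,
    KmerIndex,
    build_index,
    classify_kmers,
    pair_kmers,
)

logger = logging.getLogger("xenosplit")


@dataclass
class PipelineConfig:
    """Knobs of the full synthetic run."""

    n_genes: int = 2000
    stroma_proportion: float = 0.3
    k: int = 25
    min_avg_cpm: float = 2.0
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    shrink_weight: float = 0.5
    microdissected_n_per_group: int = 10
    design: CohortDesign = field(default_factory=CohortDesign)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = CohortDesign(**raw.pop("design", {}))
        return cls(design=design, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["design"]["passages"] is not None:
            d["design"]["passages"] = list(d["design"]["passages"])
        return d


# --------------------------------------------------------------------------
# Per-sample pipelines
# --------------------------------------------------------------------------


def run_patient_pipeline(
    reads: SampleReads, gmap: GeneKmerMap, kmers=None
) -> tuple[np.ndarray, dict]:
    """Quantify every read against the graft reference (no classification)."""
    vec, unassigned = count_sample(gmap, reads.mate1, reads.mate2, kmers=kmers)
    return vec, {"n_reads": reads.n_reads, "unassigned": unassigned}


def run_pdx_pipeline(
    reads: SampleReads, index: KmerIndex, gmap: GeneKmerMap, kmers=None
) -> tuple[np.ndarray, dict, ClassificationResult]:
    """Classify, keep the human portion (graft/ambiguous/both), quantify.

    The pooled k-mers are computed once and shared between classification
    and gene assignment (the index and the gene map use the same k).
    """
    if kmers is None:
        kmers = pair_kmers(reads.mate1, reads.mate2, index.k)
    cls = classify_kmers(index, *kmers)
    retained = cls.retained_mask()
    vec, unassigned = count_sample(
        gmap, reads.mate1, reads.mate2, retained_mask=retained, kmers=kmers
    )
    report = {
        "n_reads": reads.n_reads,
        "retained": int(retained.sum()),
        "unassigned": unassigned,
        "tallies": cls.tallies(),
    }
    return vec, report, cls


# --------------------------------------------------------------------------
# Workflow A: pipeline-sensitivity control
# --------------------------------------------------------------------------


def pipeline_sensitivity_control(
    donor_reads: Sequence[SampleReads],
    index: KmerIndex,
    gmap: GeneKmerMap,
    genes: Sequence[GenePair],
    min_avg_cpm: float = 2.0,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    classify: bool = True,
) -> dict:
    """Process donor samples through both pipelines and flag artifact genes.

    Pairing for the differential test is the sample itself (each donor
    contributes one column per pipeline).  With ``classify=False`` the PDX
    arm skips classification, which must yield identical counts — a null
    control.
    """
    from .quantify import assign_kmers

    samples, cols, meta_records = [], [], {}
    classification_reports = {}
    patient_vectors = {}
    for reads in donor_reads:
        kmers = pair_kmers(reads.mate1, reads.mate2, gmap.k)
        assigned = assign_kmers(gmap, *kmers)
        ok = assigned >= 0
        vec_patient = np.bincount(assigned[ok], minlength=gmap.n_genes).astype(np.int64)
        patient_vectors[reads.sample_id] = vec_patient
        if classify:
            cls = classify_kmers(index, *kmers)
            retained = cls.retained_mask()
            # the PDX arm assigns the same reads, so its counts equal the
            # patient-arm counts minus the assignments of dropped reads
            dropped = assigned[ok & ~retained]
            vec_pdx = vec_patient - np.bincount(
                dropped, minlength=gmap.n_genes
            ).astype(np.int64)
            classification_reports[reads.sample_id] = {
                "n_reads": reads.n_reads,
                "retained": int(retained.sum()),
                "tallies": cls.tallies(),
            }
        else:
            vec_pdx = vec_patient.copy()
        for arm, vec in (("patient", vec_patient), ("pdx", vec_pdx)):
            sid = f"{reads.sample_id}|{arm}"
            samples.append(sid)
            meta_records[sid] = {
                "patient_id": reads.sample_id,
                "tissue": "donor",
                "pipeline": arm,
                "passage": None,
            }
            cols.append(vec)
    counts = CountMatrix(
        np.stack(cols, axis=1),
        [g.gene_id for g in genes],
        samples,
        make_meta(meta_records),
    )
    filtered = filter_low_expression(counts, min_avg_cpm)
    de = nb_test(
        filtered,
        condition="pipeline",
        levels=("pdx", "patient"),
        pair_on="patient_id",
        alpha=alpha,
        lfc_threshold=lfc_threshold,
    )
    called = call_degs(de, alpha=alpha, lfc=lfc_threshold)
    artifacts = called["up"] | called["down"]
    scores = conservation_from_genes(genes)
    attribution = compare_flagged_vs_background(
        artifacts, list(filtered.genes), scores
    )
    return {
        "counts": counts,
        "filtered_genes": list(filtered.genes),
        "de": de,
        "artifact_genes": artifacts,
        "artifact_fraction": len(artifacts) / len(filtered.genes),
        "attribution": attribution,
        "classification": classification_reports,
        "patient_vectors": patient_vectors,
    }


# --------------------------------------------------------------------------
# Workflow B: donor-vs-PDX differential genes + concordance + enrichment
# --------------------------------------------------------------------------


def build_cohort_counts(
    genes: Sequence[GenePair],
    design: CohortDesign,
    read_sets,
    index: KmerIndex,
    gmap: GeneKmerMap,
    precomputed: dict | None = None,
) -> tuple[CountMatrix, dict]:
    """Quantify a cohort: donor samples via the patient pipeline, PDX samples
    via the classification-filtered PDX pipeline.

    ``precomputed`` may map sample ids to already-quantified count vectors
    (e.g. the donor patient-pipeline vectors from the sensitivity control).
    """
    precomputed = precomputed or {}
    samples, cols, meta_records, reports = [], [], {}, {}
    for reads in read_sets:
        sid = reads.sample_id
        pid, tissue = sid.split("_")[0], sid.split("_")[1]
        if sid in precomputed:
            vec, report = precomputed[sid], {"n_reads": reads.n_reads}
        elif tissue == "pdx":
            vec, report, _ = run_pdx_pipeline(reads, index, gmap)
        else:
            vec, report = run_patient_pipeline(reads, gmap)
        reports[sid] = report
        samples.append(sid)
        meta_records[sid] = {
            "patient_id": pid,
            "tissue": tissue,
            "pipeline": "pdx" if tissue == "pdx" else "patient",
            "passage": design.pdx_passages()[int(pid[1:]) - 1] if tissue == "pdx" else None,
        }
        cols.append(vec)
    counts = CountMatrix(
        np.stack(cols, axis=1),
        [g.gene_id for g in genes],
        samples,
        make_meta(meta_records),
    )
    return counts, reports


def run_xdg_workflow(
    cohort_counts: CountMatrix,
    genes: Sequence[GenePair],
    artifact_genes: set,
    config: PipelineConfig,
    microdissected_seed: int = 12345,
) -> dict:
    """Donor-vs-PDX differential genes, concordance and stroma-overlap tests.

    The expression filter is applied first, then the artifact genes from the
    pipeline-sensitivity control are excluded, then the patient-paired NB
    test is run.  Concordance is evaluated before and after excluding the
    called XDGs; the stroma-overlap enrichment compares XDGs with the
    differential list of a synthetic micro-dissected stroma/epithelium
    cohort on the universe of genes surviving both analyses' filters.
    """
    filtered = filter_low_expression(cohort_counts, config.min_avg_cpm)
    n_filtered = len(filtered.genes)
    tested = filtered.subset_genes(
        np.array([g not in artifact_genes for g in filtered.genes])
    )
    de = paired_nb_test(
        tested,
        condition="tissue",
        levels=("pdx", "donor"),
        pair_on="patient_id",
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
        shrink_weight=config.shrink_weight,
    )
    called = call_degs(de, alpha=config.alpha, lfc=config.lfc_threshold)
    xdgs = called["up"] | called["down"]

    # concordance before/after XDG exclusion (on the filtered matrix)
    expr = log_cpm(filtered)
    pairs = donor_pdx_pairs(filtered.meta)
    correlations = correlation_before_after(
        expr, pairs, exclude_before=None, exclude_after=xdgs
    )
    clustering_before = cluster_alignment(expr, pairs, exclude=None)
    clustering_after = cluster_alignment(expr, pairs, exclude=xdgs)

    pdx_samples = [p for _, p in pairs]
    passages = filtered.meta.loc[pdx_samples, "passage"].to_numpy(dtype=float)
    if np.unique(passages[~np.isnan(passages)]).size >= 4:
        passage = passage_association(expr[pdx_samples], passages)
    else:  # too few distinct passages for a meaningful association
        passage = None

    # stroma/epithelium emulation and overlap enrichment
    micro = simulate_microdissected(
        genes,
        n_per_group=config.microdissected_n_per_group,
        seed=microdissected_seed,
    )
    micro_filtered = filter_low_expression(micro, config.min_avg_cpm)
    micro_de = unpaired_nb_test(
        micro_filtered,
        condition="tissue",
        levels=("stroma", "epithelium"),
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
    )
    micro_called = call_degs(micro_de, alpha=config.alpha, lfc=config.lfc_threshold)
    ts_te_degs = micro_called["up"] | micro_called["down"]
    universe = sorted(set(tested.genes) & set(micro_filtered.genes))
    overlap = hypergeom_overlap(
        xdgs & set(universe), ts_te_degs & set(universe), universe
    )
    return {
        "n_filtered_genes": n_filtered,
        "n_tested_genes": len(tested.genes),
        "n_artifact_excluded": n_filtered - len(tested.genes),
        "de": de,
        "xdg_up": called["up"],
        "xdg_down": called["down"],
        "down_fraction": called["down_fraction"],
        "correlations": correlations,
        "clustering_before": clustering_before,
        "clustering_after": clustering_after,
        "passage": passage,
        "micro_de": micro_de,
        "ts_te_degs": ts_te_degs,
        "overlap": overlap,
        "filtered_counts": filtered,
    }


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------


def simulate_cohort(config: PipelineConfig, seed: int | None = None):
    """Generate gene pairs, truth counts and the k-mer structures for a run."""
    design = config.design
    if seed is not None:
        design = CohortDesign(**{**asdict(design), "seed": seed})
    genes = simulate_gene_pairs(
        config.n_genes,
        stroma_proportion=config.stroma_proportion,
        seed=design.seed,
    )
    truth_counts = simulate_counts(genes, design)
    index = build_index(
        [g.graft_seq for g in genes], [g.host_seq for g in genes], k=config.k
    )
    gmap = build_gene_kmer_map(genes, k=config.k)
    return genes, design, truth_counts, index, gmap


def run_all(
    config: PipelineConfig | None = None,
    outdir=None,
    seed: int | None = None,
) -> dict:
    """The full synthetic study: simulate, control, XDG workflow, reports."""
    config = config or PipelineConfig()
    genes, design, truth_counts, index, gmap = simulate_cohort(config, seed)
    donor_ids = [s for s in truth_counts.samples if s.endswith("donor")]
    donor_reads = list(
        simulate_reads(genes, design, truth_counts, samples=donor_ids)
    )
    control = pipeline_sensitivity_control(
        donor_reads,
        index,
        gmap,
        genes,
        min_avg_cpm=config.min_avg_cpm,
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
    )
    read_sets = simulate_reads(genes, design, truth_counts)
    cohort_counts, reports = build_cohort_counts(
        genes,
        design,
        read_sets,
        index,
        gmap,
        precomputed=control["patient_vectors"],
    )
    xdg = run_xdg_workflow(
        cohort_counts,
        genes,
        control["artifact_genes"],
        config,
        microdissected_seed=design.seed + 12345,
    )
    result = {
        "genes": genes,
        "design": design,
        "truth_counts": truth_counts,
        "cohort_counts": cohort_counts,
        "quantification_reports": reports,
        "control": control,
        "xdg": xdg,
    }
    if outdir is not None:
        write_run_outputs(result, config, Path(outdir))
    return result


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def write_manifest(path, config: PipelineConfig, extra: dict | None = None) -> None:
    manifest = {
        "tool": "xenosplit",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def write_run_outputs(result: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result["cohort_counts"].to_tsv(
        outdir / "counts.tsv", outdir / "samples.tsv"
    )
    result["control"]["de"].drop(columns=["gene_id"]).to_csv(
        outdir / "pipeline_control_de.tsv", sep="\t"
    )
    xdg = result["xdg"]
    xdg["de"].drop(columns=["gene_id"]).to_csv(outdir / "xdg_de.tsv", sep="\t")
    xdg["correlations"].to_csv(outdir / "pair_correlations.tsv", sep="\t", index=False)
    (outdir / "dendrogram_before.nwk").write_text(xdg["clustering_before"].newick + "\n")
    (outdir / "dendrogram_after.nwk").write_text(xdg["clustering_after"].newick + "\n")
    if xdg["passage"] is not None:
        xdg["passage"].drop(columns=["gene_id"]).to_csv(
            outdir / "passage_assoc.tsv", sep="\t"
        )
    summary = {
        "n_artifact_genes": len(result["control"]["artifact_genes"]),
        "artifact_fraction": result["control"]["artifact_fraction"],
        "n_xdg_up": len(xdg["xdg_up"]),
        "n_xdg_down": len(xdg["xdg_down"]),
        "down_fraction": xdg["down_fraction"],
        "mean_r_before": xdg["correlations"].attrs["mean_r_before"],
        "mean_r_after": xdg["correlations"].attrs["mean_r_after"],
        "aligned_before": xdg["clustering_before"].aligned,
        "aligned_after": xdg["clustering_after"].aligned,
        "n_pairs": xdg["clustering_after"].total,
        "overlap_k": xdg["overlap"].k_overlap,
        "overlap_p": xdg["overlap"].pvalue,
        "overlap_odds_ratio": xdg["overlap"].odds_ratio,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    write_manifest(
        outdir / "manifest.json",
        config,
        extra={
            "input_hashes": {
                "truth_counts": _hash_array(result["truth_counts"].counts),
                "cohort_counts": _hash_array(result["cohort_counts"].counts),
            },
            "seed": result["design"].seed,
        },
    )
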
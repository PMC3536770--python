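"""Pipeline configuration, orchestration, and shared readers/writers.

The pipeline chains normalize -> diffexpr -> cluster -> meta -> enrich ->
footprint, either on synthetic inputs (seeded, fully reproducible) or on
user-supplied files.  All numeric defaults in :class:`PipelineConfig` are the
study's published settings; every override is logged.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import diffexpr, enrich, footprint, meta, normalize, synthio
from .errors import InvalidConfigError, InvalidInputError, PipelineStageError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "de", "cluster", "crosstab", "enrich", "footprint")


@dataclass
class PipelineConfig:
    """All pipeline settings; numeric defaults are the published values."""

    outdir: str = "andropipe_out"
    seed: int = 0

    # thresholds (published defaults)
    fdr: float = 0.01
    alpha_global: float = 0.01
    filter_multiple: float = 3.0
    filter_frac: float = 0.20
    css_min: float = 0.8
    mss_min: float = 0.8
    conservation_min: float = 0.8
    enrichment_p: float = 1e-6
    min_genes: int = 3
    osir: float = 0.95
    k: int = 4

    # synthetic-mode sizes
    n_clones: int = 8000
    frac_de: float = 0.05
    effect_low: float = 2.0
    effect_high: float = 8.0
    n_genome_genes: int = 12
    n_go_terms: int = 40

    # file-mode inputs (synthetic mode when signal_s is unset)
    signal_s: str | None = None
    signal_v: str | None = None
    samples: str | None = None
    genome_fasta: str | None = None
    tss_bed: str | None = None
    conservation_bedgraph: str | None = None
    matrices: str | None = None

    # stage toggles
    run_footprint: bool = True
    run_enrich: bool = True

    @property
    def synthetic(self) -> bool:
        return self.signal_s is None

    def validate(self) -> None:
        if not 0 < self.fdr < 1 or not 0 < self.alpha_global < 1:
            raise InvalidConfigError("fdr and alpha_global must be in (0, 1)")
        if self.k < 1:
            raise InvalidConfigError("k must be >= 1")
        if not self.synthetic:
            if self.signal_v is None or self.samples is None:
                raise InvalidConfigError("file mode needs signal_s, signal_v and samples")
            if self.run_footprint and not all(
                (self.genome_fasta, self.tss_bed, self.conservation_bedgraph, self.matrices)
            ):
                raise InvalidConfigError(
                    "footprint stage enabled but genome/TSS/conservation/matrices missing"
                )
        defaults = PipelineConfig()
        for name in (
            "fdr", "alpha_global", "filter_multiple", "filter_frac", "css_min",
            "mss_min", "conservation_min", "enrichment_p", "min_genes", "osir", "k",
        ):
            if getattr(self, name) != getattr(defaults, name):
                logger.warning(
                    "threshold override: %s = %r (published default %r)",
                    name, getattr(self, name), getattr(defaults, name),
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA into contig -> sequence (pyfaidx for indexed access)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed_tss(tss_table: pd.DataFrame, path) -> None:
    tss_table.to_csv(path, sep="\t", header=False, index=False)


def read_bed_tss(path, contig_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """BED6 TSS table: 0-based half-open, strand in column 6."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InvalidInputError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise InvalidInputError(f"{path}: line {lineno}: non-integer coordinates")
            if strand not in "+-":
                raise InvalidInputError(f"{path}: line {lineno}: bad strand {strand!r}")
            if contig_lengths is not None:
                if chrom not in contig_lengths:
                    raise InvalidInputError(f"{path}: line {lineno}: unknown contig {chrom!r}")
                if end > contig_lengths[chrom]:
                    raise InvalidInputError(
                        f"{path}: line {lineno}: coordinate {end} beyond contig end"
                    )
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "name": name,
                 "score": score, "strand": strand}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bedgraph(track: dict[str, np.ndarray], path, decimals: int = 4) -> None:
    """Per-base scores as bedGraph, run-length encoding equal rounded values."""
    with open(path, "w") as fh:
        for contig, arr in track.items():
            vals = np.round(np.asarray(arr, dtype=float), decimals)
            if vals.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [vals.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{vals[s]:g}\n")


def read_bedgraph(path, contig_lengths: dict[str, int]) -> footprint.ConservationTrack:
    """bedGraph (0-based half-open) into per-base arrays; gaps score 0."""
    scores = {c: np.zeros(n) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise InvalidInputError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields
            try:
                start, end, value = int(start), int(end), float(value)
            except ValueError:
                raise InvalidInputError(f"{path}: line {lineno}: malformed values")
            if chrom not in scores:
                raise InvalidInputError(f"{path}: line {lineno}: unknown contig {chrom!r}")
            if end > len(scores[chrom]):
                raise InvalidInputError(f"{path}: line {lineno}: coordinate beyond contig end")
            scores[chrom][start:end] = value
    return footprint.ConservationTrack(scores)


def write_signal_matrix(sig: normalize.SignalMatrix, outdir: Path) -> None:
    sig.S.to_csv(outdir / "signal_S.tsv", sep="\t", index_label="clone")
    sig.V.to_csv(outdir / "signal_V.tsv", sep="\t", index_label="clone")
    pd.DataFrame({"group": sig.groups, "background": sig.B}).to_csv(
        outdir / "samples.tsv", sep="\t", index_label="sample"
    )


def read_signal_matrix(s_path, v_path, samples_path) -> normalize.SignalMatrix:
    S = pd.read_csv(s_path, sep="\t", index_col=0)
    V = pd.read_csv(v_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return normalize.SignalMatrix(S=S, V=V, B=samples["background"], groups=samples["group"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, upto: str = "footprint") -> dict:
    """Run the pipeline through ``upto`` and write the report bundle.

    Emits, under ``config.outdir``: the (synthetic) inputs, the normalized
    expression matrix, a clone-level DE/cluster/specificity table, a
    cross-tab of response clusters against the developmental atlas, an
    enrichment table, a conserved-hit table with candidate direct targets,
    and a run manifest.  Reruns with the same config are byte-identical.
    """
    if upto not in STAGES:
        raise InvalidConfigError(f"unknown stage {upto!r}")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2**31)) for s in STAGES}
    results: dict = {"config": config}

    # --- inputs -----------------------------------------------------------
    if config.synthetic:
        sig, truth = synthio.simulate_experiment(
            n_clones=config.n_clones,
            frac_de=config.frac_de,
            effect_range=(config.effect_low, config.effect_high),
            seed=stage_seeds["simulate"],
        )
        write_signal_matrix(sig, outdir)
        truth_rows = [
            {"clone": c, **{k: v for k, v in rec.items() if k != "multipliers"}}
            for c, rec in truth.de_clones.items()
        ]
        pd.DataFrame(truth_rows, columns=["clone", "effect", "direction", "pattern"]).to_csv(
            outdir / "truth_de.tsv", sep="\t", index=False
        )
    else:
        sig = read_signal_matrix(config.signal_s, config.signal_v, config.samples)
        truth = None
    results["signal"] = sig
    logger.info("inputs: %d clones x %d samples", *sig.S.shape)
    if upto == "simulate":
        _write_manifest(config, outdir)
        return results

    # --- normalize --------------------------------------------------------
    try:
        expr = normalize.normalize_chain(
            sig, multiple=config.filter_multiple, frac=config.filter_frac
        )
    except Exception as exc:
        raise PipelineStageError(f"stage 'normalize' failed: {exc}") from exc
    expr.values.to_csv(outdir / "expression.tsv", sep="\t", index_label="clone")
    results["expression"] = expr
    logger.info("normalize: %d well-measured clones", expr.values.shape[0])
    if upto == "normalize":
        _write_manifest(config, outdir)
        return results

    # --- differential expression -----------------------------------------
    try:
        de = diffexpr.de_analysis(
            expr, sig.groups, fdr=config.fdr, alpha_global=config.alpha_global
        )
    except Exception as exc:
        raise PipelineStageError(f"stage 'de' failed: {exc}") from exc
    results["de"] = de
    responsive = de.index[de["de"]]
    logger.info("de: %d responsive clones at FDR %g", len(responsive), config.fdr)
    if upto == "de":
        de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="clone")
        _write_manifest(config, outdir)
        return results

    # --- clustering -------------------------------------------------------
    try:
        if len(responsive) < config.k:
            raise InvalidInputError(
                f"only {len(responsive)} responsive clones for k={config.k}"
            )
        rows = _cluster.standardize_rows(expr.values.loc[responsive])
        model = _cluster.pam_cluster(rows, k=config.k)
        group_means_unlogged = (
            (2.0 ** expr.values.loc[responsive]).T.groupby(sig.groups).mean().T
        )
        fc = group_means_unlogged.div(group_means_unlogged["control"], axis=0)
        _cluster.label_clusters(model, fc)
        semantic = pd.Series(
            [model.labels[c] for c in model.assignment], index=responsive, name="cluster"
        )
    except Exception as exc:
        raise PipelineStageError(f"stage 'cluster' failed: {exc}") from exc
    results["cluster_model"] = model
    results["clusters"] = semantic
    de["cluster"] = semantic.reindex(de.index)
    de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="clone")
    summaries = _cluster.cluster_fold_changes(group_means_unlogged, semantic)
    summaries.to_csv(outdir / "cluster_fold_changes.tsv", sep="\t")
    if upto == "cluster":
        _write_manifest(config, outdir)
        return results

    # --- cross-tabulation against the developmental atlas -----------------
    try:
        atlas = synthio.simulate_dev_atlas(
            list(expr.values.index), seed=stage_seeds["crosstab"]
        )
        tab = meta.cross_tabulate(semantic, atlas)
        shift = meta.germline_shift_summary(tab)
    except Exception as exc:
        raise PipelineStageError(f"stage 'crosstab' failed: {exc}") from exc
    results["atlas"] = atlas
    results["crosstab"] = tab
    results["germline_shift"] = shift
    tab.table.to_csv(outdir / "crosstab.tsv", sep="\t")
    logger.info(
        "crosstab: %d clones with both labels; somatic/germline = %s",
        tab.n_both, meta.compartment_counts(tab),
    )
    if upto == "crosstab":
        _write_manifest(config, outdir)
        return results

    # --- GO enrichment ----------------------------------------------------
    if config.run_enrich:
        try:
            universe = set(expr.values.index)
            largest = semantic.value_counts().idxmax()
            planted_genes = list(semantic.index[semantic == largest])
            dag, annotations, planted_term = synthio.simulate_go(
                n_terms=config.n_go_terms,
                genes=sorted(universe),
                planted_term_size=min(len(planted_genes), 20),
                seed=stage_seeds["enrich"],
                planted_genes=sorted(planted_genes),
            )
            propagated = enrich.propagate_annotations(annotations, dag)
            records = []
            for label in sorted(semantic.unique()):
                cluster_genes = set(semantic.index[semantic == label])
                res = enrich.enrich_cluster(
                    cluster_genes, propagated, universe, dag=dag, propagate=False
                )
                enrich.osir_filter(
                    res, dag, propagated, cluster_genes,
                    cutoff=config.osir, enriched_p=config.enrichment_p,
                )
                enrich.report_enriched(
                    res, p_cutoff=config.enrichment_p, min_genes=config.min_genes
                )
                for r in res:
                    records.append(
                        {"cluster": label, "term": r.term, "observed": r.observed,
                         "expected": round(r.expected, 4), "term_size": r.term_size,
                         "universe": r.universe_size, "p_over": r.p_over,
                         "p_under": r.p_under, "osir": r.osir, "reported": r.reported}
                    )
            enrich_table = pd.DataFrame.from_records(records)
            enrich_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enrich_table
            results["planted_term"] = planted_term
        except Exception as exc:
            raise PipelineStageError(f"stage 'enrich' failed: {exc}") from exc
    if upto == "enrich" or not config.run_footprint:
        _write_manifest(config, outdir)
        return results

    # --- footprinting -----------------------------------------------------
    try:
        matrices = (
            footprint.read_transfac(config.matrices)
            if config.matrices
            else synthio.synthetic_matrices(seed=0)
        )
        if config.synthetic:
            gene_clones = list(responsive[: config.n_genome_genes])
            frng = np.random.default_rng(stage_seeds["footprint"])
            plants = []
            for i, _ in enumerate(gene_clones):
                if i % 3 == 2:  # a third of promoters stay empty
                    continue
                m = matrices[int(frng.integers(len(matrices)))]
                # mix proximal and distal instances so candidate calling is exercised
                rel = int(frng.integers(-1800, 380)) if i % 2 == 0 else int(frng.integers(-9000, -2100))
                plants.append(synthio.PlantedMotif(i, m.id, rel))
            genome, tss_table, track_arrays, ftruth = synthio.simulate_genome(
                n_genes=len(gene_clones),
                planted_motifs=plants,
                seed=stage_seeds["footprint"],
                matrices=matrices,
            )
            gene_map = dict(zip(tss_table["name"], gene_clones))
            write_fasta(genome, outdir / "genome.fa")
            write_bed_tss(tss_table, outdir / "tss.bed")
            write_bedgraph(track_arrays, outdir / "conservation.bedGraph")
            footprint.write_transfac(matrices, outdir / "matrices.transfac")
            track = footprint.ConservationTrack(track_arrays)
        else:
            genome = read_fasta(config.genome_fasta)
            lengths = {c: len(s) for c, s in genome.items()}
            tss_table = read_bed_tss(config.tss_bed, lengths)
            track = read_bedgraph(config.conservation_bedgraph, lengths)
            gene_map = {n: n for n in tss_table["name"]}
            ftruth = None
        all_hits = []
        for _, row in tss_table.iterrows():
            region = footprint.promoter_region(
                genome, row["name"], row["chrom"], row["strand"], int(row["start"])
            )
            for m in matrices:
                all_hits.extend(
                    footprint.scan_promoter(
                        m, region, css_min=config.css_min, mss_min=config.mss_min
                    )
                )
        conserved = footprint.conservation_filter(
            all_hits, track, min_score=config.conservation_min
        )
        conserved = footprint.bin_hits(conserved)
        compartment = {}
        for gene, clone in gene_map.items():
            label = results["atlas"].labels.get(clone) if "atlas" in results else None
            compartment[gene] = meta.classify_compartment(label)[0] if label else "unknown"
        responsive_map = {g: (gene_map[g] in set(responsive)) for g in gene_map}
        candidates = footprint.candidate_direct_targets(conserved, compartment, responsive_map)
        hit_table = pd.DataFrame(
            [
                {"gene": h.gene_id, "clone": gene_map.get(h.gene_id, ""),
                 "matrix": h.matrix_id, "contig": h.contig, "start": h.start,
                 "end": h.end, "strand": h.strand, "rel_start": h.rel_start,
                 "sequence": h.sequence, "mss": round(h.mss, 4), "css": round(h.css, 4),
                 "conservation": round(h.conservation, 4), "bin": h.bin,
                 "proximal": h.proximal,
                 "proximal_somatic": bool(h.proximal and compartment.get(h.gene_id) == "somatic")}
                for h in conserved
            ]
        )
        hit_table.to_csv(outdir / "are_hits.tsv", sep="\t", index=False)
        pd.Series(candidates, name="gene").to_csv(
            outdir / "candidate_targets.tsv", sep="\t", index=False
        )
        results["hits"] = conserved
        results["candidates"] = candidates
        results["footprint_truth"] = ftruth
        logger.info(
            "footprint: %d conserved hits, %d candidate direct targets",
            len(conserved), len(candidates),
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"stage 'footprint' failed: {exc}") from exc

    _write_manifest(config, outdir)
    return results


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
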
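"""End-to-end driver: simulate -> detect -> consensus -> differential -> enrich.

The driver is a pure composition of the module operations: running it with
a configuration is equivalent to calling the stages by hand with the same
parameters, and the same configuration plus seed reproduces every output
byte-identically.  Outputs are plain-text TSV/BED files in the configured
output directory, plus a run manifest with per-stage row counts.
"""

from __future__ import annotations

import copy
import hashlib
import json
from datetime import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atac import (
    build_consensus,
    detect_outlier_peaks,
    annotate_peaks,
    filter_low_counts,
    tmm_factors,
    voom_transform,
    weighted_counts,
)
from .differential import GroupModelSpec, classify_genes, run_differential
from .enrichment import GeneSet, run_enrichment_suite
from .expression import (
    flag_detected_features,
    reduce_transcriptome,
    second_pass,
    upper_quartile_log,
)
from .io import write_bed, write_consensus_bed, write_matrix
from .panel import InvalidConfigError
from .simulate import (
    PanelConfig,
    default_truth,
    generate_panel,
    simulate_atac,
    simulate_expression,
    synthetic_gene_models,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "clonediff_run",
    "panel": {"n_wt": 4, "n_exon4_high": 3, "n_exon4_low": 4, "n_exon6": 5, "n_double": 8},
    "expression": {
        "n_genes": 200,
        "transcripts_per_gene": 2,
        "dispersion": 0.4,
        "dropped_fraction": 0.1,
    },
    "atac": {"n_peaks": 300, "peak_width": 500, "jitter": 50, "dispersion": 0.1},
    "truth": {
        "n_de": 30,
        "de_effect": 2.0,
        "de_contrast": "H4:2-vs-0",
        "n_gradient": 20,
        "gradient_slope": 150.0,
        "n_outliers": 5,
        "enriched_set_size": 40,
        "enriched_de_fraction": 0.6,
    },
    "detection": {"min_reads": 1, "clone_fraction": 0.5},
    "normalize": {"pseudo": 1.0, "log_base": 2.0},
    "consensus": {"min_clones": 2, "min_score_per_million": 1.0},
    "filter": {"min_reads": 10, "sample_fraction": 0.5},
    "diff": {"hypotheses": ["H4"], "alpha": 0.05, "fc_delta": 0.001},
    "enrich": {"modes": ["DE", "DA-proximal", "DE-or-DA"]},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    settings: dict = field(repr=False)

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in (overrides or {}).items():
            if key not in cfg:
                raise InvalidConfigError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict):
                unknown = set(val) - set(cfg[key])
                if unknown:
                    raise InvalidConfigError(f"unknown keys under {key!r}: {sorted(unknown)}")
                cfg[key].update(val)
            else:
                cfg[key] = val
        return cls(cfg)

    def __getitem__(self, key):
        return self.settings[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.settings, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict = field(default_factory=dict)
    created: str = field(default_factory=lambda: datetime.now().isoformat())

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = {k: int(v) for k, v in counts.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "config_hash": self.config_hash,
                 "created": self.created, "stages": self.stages},
                fh, indent=2, sort_keys=True,
            )


def run_pipeline(config: PipelineConfig, outdir=None) -> RunManifest:
    """Run all stages on a simulated panel and write every stage output."""
    cfg = config.settings
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(version=__version__, config_hash=config.hash())

    # --- simulate -----------------------------------------------------
    panel = generate_panel(PanelConfig(**cfg["panel"], seed=seed))
    truth = default_truth(
        n_genes=cfg["expression"]["n_genes"],
        n_peaks=cfg["atac"]["n_peaks"],
        seed=seed,
        clones=panel.clones,
        **cfg["truth"],
    )
    sim = simulate_expression(
        panel,
        n_genes=cfg["expression"]["n_genes"],
        transcripts_per_gene=cfg["expression"]["transcripts_per_gene"],
        truth=truth,
        dispersion=cfg["expression"]["dispersion"],
        dropped_fraction=cfg["expression"]["dropped_fraction"],
        seed=int(np.random.default_rng([seed, 1]).integers(2**31)),
    )
    calls = simulate_atac(
        panel,
        n_peaks=cfg["atac"]["n_peaks"],
        truth=truth,
        peak_width=cfg["atac"]["peak_width"],
        jitter=cfg["atac"]["jitter"],
        dispersion=cfg["atac"]["dispersion"],
        seed=int(np.random.default_rng([seed, 2]).integers(2**31)),
    )
    panel.to_tsv(out / "panel.tsv")
    truth.to_tsv(out / "truth.tsv")
    write_matrix(sim.expression.tpm, out / "tpm.tsv", index_label="transcript")
    write_matrix(sim.coverage.read_support, out / "feature_support.tsv", index_label="feature")
    sim.catalog.to_tsv(out / "features.tsv", out / "transcript_to_gene.tsv")
    for clone, tab in calls.items():
        write_bed(tab, out / f"peaks_{clone}.bed")
    manifest.record(
        "simulate",
        clones=len(panel),
        transcripts=sim.expression.tpm.shape[0],
        peaks=cfg["atac"]["n_peaks"],
    )

    # --- expression detection + normalization -------------------------
    det = cfg["detection"]
    feat_flags = flag_detected_features(
        sim.coverage, min_reads=det["min_reads"], clone_fraction=det["clone_fraction"]
    )
    reduced = reduce_transcriptome(sim.catalog, feat_flags)
    passed = second_pass(sim.expression, reduced, clone_fraction=det["clone_fraction"])
    genes_norm = upper_quartile_log(
        passed.genes, pseudo=cfg["normalize"]["pseudo"], log_base=cfg["normalize"]["log_base"]
    )
    write_matrix(genes_norm.tpm, out / "gene_tpm.tsv", index_label="gene")
    write_matrix(genes_norm.normalized_log, out / "gene_log_expression.tsv", index_label="gene")
    manifest.record(
        "expression",
        features_in=len(sim.catalog.features),
        transcripts_retained=len(reduced.transcript_to_gene),
        genes_expressed=int(passed.genes.detected.sum()),
    )

    # --- ATAC consensus + normalization -------------------------------
    cons_cfg = cfg["consensus"]
    consensus = build_consensus(
        calls,
        min_clones=cons_cfg["min_clones"],
        min_score_per_million=cons_cfg["min_score_per_million"],
    )
    counts = weighted_counts(consensus, calls)
    counts = filter_low_counts(
        counts, min_reads=cfg["filter"]["min_reads"],
        sample_fraction=cfg["filter"]["sample_fraction"],
    )
    flags, excluded = detect_outlier_peaks(counts)
    counts_clean = counts.drop(index=excluded)
    factors = tmm_factors(counts_clean)
    labels4 = panel.groups(cfg["diff"]["hypotheses"][0])
    log_cpm, weights = voom_transform(counts_clean, factors, groups=labels4)
    gene_models = synthetic_gene_models(cfg["expression"]["n_genes"])
    annotations = annotate_peaks(
        [p for p in consensus if p.name in set(counts_clean.index)], gene_models
    )
    write_consensus_bed(consensus, out / "consensus_peaks.bed")
    write_matrix(counts, out / "peak_counts.tsv", index_label="peak")
    write_matrix(log_cpm, out / "peak_log_cpm.tsv", index_label="peak")
    annotations.to_csv(out / "peak_annotations.tsv", sep="\t", index=False)
    manifest.record(
        "atac",
        consensus_peaks=len(consensus),
        peaks_after_count_filter=counts.shape[0],
        outlier_peaks_excluded=len(excluded),
    )

    # --- differential --------------------------------------------------
    alpha = cfg["diff"]["alpha"]
    gene_linear = genes_norm.tpm.div(genes_norm.scale_factors, axis=1)
    de_tables, da_tables = [], []
    for hyp in cfg["diff"]["hypotheses"]:
        spec = GroupModelSpec(hyp, panel.groups(hyp))
        de = run_differential(
            genes_norm.normalized_log, spec, linear_values=gene_linear,
            alpha=alpha, fc_delta=cfg["diff"]["fc_delta"],
        )
        de["hypothesis"] = hyp
        da = run_differential(log_cpm, spec, weights=weights, alpha=alpha)
        da["hypothesis"] = hyp
        de_tables.append(de)
        da_tables.append(da)
    de_all = pd.concat(de_tables, ignore_index=True)
    da_all = pd.concat(da_tables, ignore_index=True)
    de_all.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    da_all.to_csv(out / "differential_accessibility.tsv", sep="\t", index=False)
    manifest.record(
        "differential",
        expression_tests=len(de_all),
        accessibility_tests=len(da_all),
        de_calls=int(de_all["significant"].sum()),
        dap_calls=int(da_all["significant"].sum()),
    )

    # --- enrichment -----------------------------------------------------
    classes = classify_genes(de_all, da_all, annotations, alpha=alpha)
    sets = [GeneSet("planted_set", frozenset(truth.enriched_set_genes))]
    enr = run_enrichment_suite(classes, sets, modes=cfg["enrich"]["modes"])
    classes.to_csv(out / "gene_classification.tsv", sep="\t", index=False)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    manifest.record("enrichment", tests=len(enr))

    manifest.to_json(out / "manifest.json")
    return manifest
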
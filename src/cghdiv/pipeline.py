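"""End-to-end orchestration: simulate/read -> preprocess -> detect ->
calibrate -> enrich, with a JSON summary per run.

The configuration is a single YAML/JSON document.  Each species entry names
either a ``simulate`` block (species profile plus generator overrides) or a
``paths`` block (scan files and an annotation table) - never both.
Simulated species share one platform (gene assignment, probe properties, GO
annotation) keyed by the run seed.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import detection as det
from . import enrichment as enr
from . import preprocess as pre
from . import synthetic as syn
from .errors import ConfigurationError

log = logging.getLogger("cghdiv")


@dataclass
class SpeciesSpec:
    name: str
    simulate: dict | None = None
    paths: dict | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ConfigurationError(
                f"species {self.name!r}: exactly one of 'simulate' or 'paths' required"
            )


@dataclass
class PipelineConfig:
    seed: int = 0
    species: list[SpeciesSpec] = field(default_factory=list)
    generator: dict = field(default_factory=dict)  # shared GeneratorConfig overrides
    n_deep_genes: int = 0
    deep_pct_id: float = 65.0
    k_sd: float = 2.0
    q_levels: tuple = (0.1, 0.05, 0.01)
    fold: float = 4.0
    go_p: float = 0.01
    loess_span: float = 0.4
    min_arrays: int = 2
    detection_window: int = 51
    vp_window: int = 301
    replication_k: tuple | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigurationError("at least one species entry is required")
        if not all(0 < q < 1 for q in self.q_levels):
            raise ConfigurationError("q_levels must lie in (0, 1)")
        if self.fold <= 1:
            raise ConfigurationError("fold must be > 1")
        if not 0 < self.go_p < 1:
            raise ConfigurationError("go_p must lie in (0, 1)")
        if self.k_sd < 0 or self.loess_span <= 0 or self.min_arrays < 1:
            raise ConfigurationError("invalid preprocessing thresholds")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        species = [
            SpeciesSpec(
                name=s["name"], simulate=s.get("simulate"), paths=s.get("paths")
            )
            for s in d.pop("species", [])
        ]
        for key in ("q_levels", "replication_k"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(species=species, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _resolve_profile(block: dict) -> syn.SpeciesProfile:
    prof = block.get("profile", "distant")
    if isinstance(prof, str):
        try:
            return syn.NAMED_PROFILES[prof]
        except KeyError:
            raise ConfigurationError(f"unknown species profile {prof!r}") from None
    return syn.SpeciesProfile(
        name=prof.get("name", "custom"),
        id_mixture=tuple(tuple(c) for c in prof["id_mixture"]),
        frac_missing_ortholog=prof.get("frac_missing_ortholog", 0.0),
    )


def _generator_config(cfg: PipelineConfig, block: dict) -> syn.GeneratorConfig:
    fields = dict(cfg.generator)
    fields.update({k: v for k, v in block.items() if k != "profile"})
    fields["seed"] = cfg.seed
    return syn.GeneratorConfig(**fields)


def _materialize(cfg: PipelineConfig) -> dict[str, tuple[pd.DataFrame, list]]:
    """Simulate or read every species: name -> (annotations, scans)."""
    deep: tuple = ()
    sim_specs = [s for s in cfg.species if s.simulate is not None]
    if cfg.n_deep_genes and sim_specs:
        gcfg0 = _generator_config(cfg, sim_specs[0].simulate)
        ann0, _ = syn.generate_feature_annotations(gcfg0, _resolve_profile(sim_specs[0].simulate))
        rng = np.random.default_rng([cfg.seed, 3])
        deep = tuple(rng.choice(sorted(set(ann0["gene_id"])), size=cfg.n_deep_genes, replace=False))

    out = {}
    for spec in cfg.species:
        if spec.simulate is not None:
            gcfg = _generator_config(cfg, spec.simulate)
            profile = _resolve_profile(spec.simulate)
            ann, truth = syn.generate_feature_annotations(
                gcfg, profile, deep_genes=deep, deep_pct_id=cfg.deep_pct_id
            )
            scans = syn.simulate_scans(ann, truth, gcfg, stream=zlib.crc32(spec.name.encode()))
        else:
            ann = syn.read_annotations(spec.paths["annotations"])
            scan_paths = spec.paths["scans"]
            if isinstance(scan_paths, str):
                scan_paths = sorted(Path().glob(scan_paths)) or sorted(
                    Path(scan_paths).glob("array_*.tsv")
                )
            scans = [pre.read_array_scan(p) for p in scan_paths]
        out[spec.name] = (ann, scans)
    return out


def _analyze_species(
    name: str, ann: pd.DataFrame, scans: list, cfg: PipelineConfig, out_dir: Path
) -> dict[str, Any]:
    sp_dir = out_dir / name
    sp_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    rm = pre.normalize_loess_conserved(
        scans, ann, span=cfg.loess_span, k_sd=cfg.k_sd, min_arrays=cfg.min_arrays
    )
    rm.write_tsv(sp_dir / "ratio_matrix.tsv")
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_df = det.fit_feature_stats(rm)
    mstats = det.shrink_variances(stats_df)
    calls = det.call_diverged(mstats, thresholds=cfg.q_levels)
    calls.to_csv(sp_dir / "divergence_calls.tsv", sep="\t", na_rep="NA")
    timings["detect"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ann_idx = ann.set_index("feature_id")
    pct_id = ann_idx["true_pct_id"].reindex(calls.index)
    div_cols = sorted(c for c in calls.columns if c.startswith("diverged_"))
    pct_div = {
        c[len("diverged_"):]: 100.0 * float(calls.loc[calls["q"].notna(), c].mean())
        for c in div_cols
    }
    curve = cal.detection_curve(calls, pct_id, window=cfg.detection_window)
    curve.to_csv(sp_dir / "detection_curve.tsv", sep="\t", index=False, na_rep="NA")

    primary = f"q{int(round(max(cfg.q_levels) * 100)):02d}"
    valid = calls["q"].notna() & pct_id.notna()
    id50 = cal.fit_id50(
        calls.loc[valid, f"diverged_{primary}"].to_numpy(), pct_id[valid].to_numpy()
    )
    lin = cal.linreg_ratio_id(calls.loc[valid, "mean_M"], pct_id[valid])
    kin = cal.kinetics_regression(
        calls.loc[valid, "mean_M"],
        pct_id[valid],
        ann_idx["gc_percent"].reindex(calls.index)[valid],
        ann_idx["probe_length_bp"].reindex(calls.index)[valid],
        ann_idx["pct_align"].reindex(calls.index)[valid],
    )
    resid = (
        calls.loc[valid, "mean_M"].to_numpy()
        - (lin.intercept + lin.slope * pct_id[valid].to_numpy())
    )
    se_mean = np.sqrt(calls.loc[valid, "s2_post"] / calls.loc[valid, "n_used"]).to_numpy()
    vp = cal.variance_partition(se_mean, resid, pct_id[valid].to_numpy(), window=cfg.vp_window)
    vp.to_csv(sp_dir / "variance_partition.tsv", sep="\t", index=False, na_rep="NA")
    crossover = cal.find_crossover(vp)

    calibration_out = {
        "logistic": {
            "intercept": id50.intercept, "slope": id50.slope,
            "id50": id50.id50, "status": id50.status,
        },
        "linreg": vars(lin),
        "kinetics": {
            "r2": kin.r2,
            "terms": {
                t: {k: float(v) for k, v in row.items()}
                for t, row in kin.table.iterrows()
            },
        },
        "crossover_pct_id": crossover,
    }
    with open(sp_dir / "calibration.json", "w") as fh:
        json.dump(calibration_out, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")

    replication = None
    if cfg.replication_k and len(rm.M.columns) >= max(cfg.replication_k):
        summary, se_table = cal.replication_power_analysis(
            rm, pct_id, k_list=cfg.replication_k, alpha=max(cfg.q_levels), seed=cfg.seed
        )
        summary.to_csv(sp_dir / "replication.tsv", sep="\t", index=False, na_rep="NA")
        se_table.to_csv(sp_dir / "replication_se.tsv", sep="\t", index=False, na_rep="NA")
        replication = summary
    timings["calibrate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    edges, names = syn.make_go_dag()
    gene_terms = {}
    for gid, terms in zip(ann["gene_id"], ann["go_terms"]):
        if isinstance(terms, str) and terms:
            gene_terms.setdefault(gid, set()).update(terms.split(";"))
    annset = enr.propagate_annotations(gene_terms, edges, names)
    analyzed_genes = set(ann_idx["gene_id"].reindex(calls.index[calls["q"].notna()]))
    universe = {g for g in analyzed_genes if g in annset.gene2terms}
    div_genes = set(
        ann_idx["gene_id"].reindex(calls.index[calls[f"diverged_{primary}"].fillna(False)])
    ) & universe
    go_summary = {"n_terms_tested": 0, "n_over": 0, "n_under": 0}
    if div_genes and universe:
        go_table = enr.hypergeom_test(div_genes, universe, annset, p_threshold=cfg.go_p)
        go_table.to_csv(sp_dir / "go_enrichment.tsv", sep="\t", index=False)
        go_summary = {
            "n_terms_tested": int(len(go_table)),
            "n_over": int(go_table["over_represented"].sum()),
            "n_under": int(go_table["under_represented"].sum()),
        }
    timings["enrich"] = time.perf_counter() - t0
    log.info("species %s stage timings: %s", name, {k: round(v, 3) for k, v in timings.items()})

    return {
        "rm": rm,
        "calls": calls,
        "annotations": ann,
        "summary": {
            "n_features": int(len(ann)),
            "n_analyzed": int(calls["q"].notna().sum()),
            "pct_diverged": pct_div,
            "id50": None if np.isnan(id50.id50) else float(id50.id50),
            "id50_status": id50.status,
            "linreg_r2": lin.r2,
            "linreg_slope": lin.slope,
            "crossover_pct_id": None if np.isnan(crossover) else float(crossover),
            "go": go_summary,
            "replication": None
            if replication is None
            else replication.to_dict(orient="records"),
        },
    }


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis for every configured species.

    Writes per-species TSV/JSON outputs plus a top-level ``summary.json``
    (per species: analyzed counts, % diverged at each q level, ID-50, R^2,
    variance-partition crossover, GO term counts) and the cross-species
    intersection of >fold-reduced genes.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    log.info("pipeline start: seed=%d, %d species", cfg.seed, len(cfg.species))

    data = _materialize(cfg)
    results = {}
    for name, (ann, scans) in data.items():
        results[name] = _analyze_species(name, ann, scans, cfg, out_dir)

    mean_m = {
        name: res["calls"]["mean_M"].dropna() for name, res in results.items()
    }
    first_ann = next(iter(results.values()))["annotations"]
    feature_to_gene = first_ann.set_index("feature_id")["gene_id"]
    pct_ids = {
        name: res["annotations"].set_index("feature_id")["true_pct_id"]
        for name, res in results.items()
    }
    sets, inter, table = enr.highly_diverged_sets(
        mean_m, feature_to_gene, fold=cfg.fold, pct_id_by_species=pct_ids
    )
    table.to_csv(out_dir / "highly_diverged_intersection.tsv", sep="\t", index=False)

    summary = {
        "seed": cfg.seed,
        "species": {name: res["summary"] for name, res in results.items()},
        "fourfold_sets": {name: len(s) for name, s in sets.items()},
        "fourfold_intersection_genes": len(inter),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    log.info("pipeline done in %.1f s", time.perf_counter() - t_start)
    return summary
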
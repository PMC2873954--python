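"""Synthetic two-color aCGH datasets with planted per-feature divergence truth.

Emulates a spotted PCR-product platform (probes ~500 bp) hybridized with
genomic DNA from the platform species against a heterologous species in a
dye-swapped replicate design.  Every downstream stage of the pipeline
(filtering, loess normalization, moderated testing, calibration, enrichment)
can be checked against the planted ground truth produced here.

The generative model for the oriented log2 hybridization ratio of feature f is

    M_{f,a} = mu_f + kinetic_f + eps_{f,a}

where mu_f = beta0 + beta_id * pctid_f is the mean structure on percent
identity, kinetic_f is a per-feature (sequence-pair specific) deviation built
from standardized GC content, percent alignment length, an %ID x GC
interaction, and a random component with SD sd_kinetic(pctid), and eps is
per-observation technical noise with SD sd_technical(pctid).  The raw ratio
on each array additionally carries a dye-orientation sign, an additive dye
bias, and a smooth intensity-dependent trend (removable by loess); channel
intensities are reconstructed from the ratio and a per-observation average
log-intensity, with additive backgrounds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

NO_HIT = "NoHit"
#: %ID assigned to missing-ortholog features when simulating hybridization.
NO_HIT_FLOOR_ID = 60.0

SCAN_COLUMNS = ["feature_id", "F635", "B635", "F532", "B532", "flag"]


def default_sd_kinetic(pct_id):
    """Kinetic-deviation SD: flat for conserved probes, grows with divergence."""
    pct_id = np.asarray(pct_id, dtype=float)
    return 0.04 + 0.012 * np.clip(95.0 - pct_id, 0.0, None)


def default_sd_technical(pct_id):
    """Per-observation technical noise SD, mildly increasing with divergence."""
    pct_id = np.asarray(pct_id, dtype=float)
    return 0.30 + 0.012 * (100.0 - pct_id)


@dataclass(frozen=True)
class SpeciesProfile:
    """Distribution of per-feature percent identity for one species contrast.

    ``id_mixture`` is a tuple of ``(weight, mean, sd)`` truncated-normal
    components on [60, 100].  ``frac_missing_ortholog`` is the proportion of
    features with no detectable ortholog; those carry a ``NoHit`` sentinel in
    the annotation and hybridize at the floor %ID.
    """

    name: str
    id_mixture: tuple[tuple[float, float, float], ...]
    frac_missing_ortholog: float = 0.0

    def __post_init__(self) -> None:
        if not self.id_mixture:
            raise ConfigurationError("id_mixture must have at least one component")
        w = np.array([c[0] for c in self.id_mixture], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"id_mixture weights must sum to 1 (got {w.sum()!r})"
            )
        for _, m, s in self.id_mixture:
            if not 60.0 <= m <= 100.0:
                raise ConfigurationError(f"component mean {m} outside [60, 100]")
            if s <= 0:
                raise ConfigurationError(f"component sd {s} must be > 0")
        if not 0.0 <= self.frac_missing_ortholog <= 1.0:
            raise ConfigurationError("frac_missing_ortholog must be in [0, 1]")


#: A closely diverged contrast (most orthologs >= 95 %ID, few missing).
CLOSE_PROFILE = SpeciesProfile(
    "close", ((0.75, 97.0, 1.2), (0.25, 93.0, 2.5)), frac_missing_ortholog=0.01
)
#: A distant contrast: conserved mode plus a long divergence tail to ~73 %ID.
DISTANT_PROFILE = SpeciesProfile(
    "distant",
    ((0.40, 96.5, 1.5), (0.35, 91.0, 3.0), (0.25, 83.0, 5.0)),
    frac_missing_ortholog=0.05,
)

NAMED_PROFILES = {"close": CLOSE_PROFILE, "distant": DISTANT_PROFILE}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_features: int = 18000
    n_arrays: int = 8
    beta0: float = -10.0
    beta_id: float = 0.10
    beta_gc: float = 0.12
    beta_align: float = 0.05
    beta_id_gc: float = -0.06
    sd_kinetic: Callable = default_sd_kinetic
    sd_technical: Callable = default_sd_technical
    dye_bias: float = 0.30
    intensity_trend_amplitude: float = 0.30
    background_mean: float = 100.0
    background_sd: float = 20.0
    frac_lowquality: float = 0.05
    conserved_n: int = 1000

    def __post_init__(self) -> None:
        if self.n_arrays < 2 or self.n_arrays % 2 != 0:
            raise ConfigurationError("n_arrays must be even and >= 2 (dye-swap pairs)")
        if self.conserved_n > self.n_features:
            raise ConfigurationError("conserved_n must be <= n_features")
        if not 0.0 <= self.frac_lowquality < 1.0:
            raise ConfigurationError("frac_lowquality must be in [0, 1)")
        probe = np.array([60.0, 80.0, 100.0])
        for fn, label in ((self.sd_kinetic, "sd_kinetic"), (self.sd_technical, "sd_technical")):
            if np.any(np.asarray(fn(probe)) < 0):
                raise ConfigurationError(f"{label} must be non-negative")


@dataclass
class ArrayScan:
    """One hybridization: per-feature two-channel intensities plus flags."""

    array_id: str
    dye_swapped: bool
    data: pd.DataFrame  # index feature_id; columns F635 B635 F532 B532 flag


# --------------------------------------------------------------------------
# toy GO ontology (fixed DAG; gene annotation is drawn by the generator)

def make_go_dag() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A small fixed GO-like DAG: 1 root, 8 mid-level terms, 24 leaves.

    Returns (edges, names); edges are child -> parent.  Some leaves have two
    parents so that ancestor propagation over a diamond is exercised.
    """
    root = "GO:0000001"
    mids = [f"GO:00001{i:02d}" for i in range(8)]
    leaves = [f"GO:00002{i:02d}" for i in range(24)]
    edges = [(m, root) for m in mids]
    for i, leaf in enumerate(leaves):
        edges.append((leaf, mids[i % 8]))
        if i % 3 == 0:
            edges.append((leaf, mids[(i + 1) % 8]))
    names = (
        [(root, "biological process")]
        + [(m, f"process group {i}") for i, m in enumerate(mids)]
        + [(t, f"process {i}") for i, t in enumerate(leaves)]
    )
    edges_df = pd.DataFrame(edges, columns=["child", "parent"])
    names_df = pd.DataFrame(names, columns=["term_id", "term_name"])
    return edges_df, names_df


def _annotate_genes(genes: Sequence[str], rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    """Assign 1-3 leaf terms to roughly half of the genes."""
    leaves = [f"GO:00002{i:02d}" for i in range(24)]
    out: dict[str, tuple[str, ...]] = {}
    for g in genes:
        if rng.random() < 0.5:
            k = int(rng.integers(1, 4))
            terms = rng.choice(leaves, size=min(k, len(leaves)), replace=False)
            out[g] = tuple(sorted(terms))
    return out


# --------------------------------------------------------------------------
# feature annotation / truth generation

def _sample_mixture(profile: SpeciesProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([c[0] for c in profile.id_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    out = np.empty(n)
    for j, (_, m, s) in enumerate(profile.id_mixture):
        idx = np.flatnonzero(comp == j)
        if idx.size:
            a, b = (60.0 - m) / s, (100.0 - m) / s
            out[idx] = stats.truncnorm.rvs(a, b, loc=m, scale=s, size=idx.size, random_state=rng)
    return out


def generate_feature_annotations(
    cfg: GeneratorConfig,
    profile: SpeciesProfile,
    deep_genes: Sequence[str] = (),
    deep_pct_id: float = 65.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the per-feature annotation table and the planted truth table.

    Platform-level properties (gene assignment, probe length, GC, GO terms)
    depend only on ``cfg.seed``, so calling this with several species profiles
    and the same config simulates multiple contrasts on one shared platform.
    Species-level properties (%ID, alignment, kinetic deviations) are drawn
    from a stream keyed by the profile name.

    ``deep_genes`` optionally plants a shared set of highly diverged genes
    (all their features forced to ~``deep_pct_id``), used to emulate genes
    with strong hybridization reduction in every heterologous species.
    """
    n = cfg.n_features
    prng = np.random.default_rng([cfg.seed, 0])
    srng = np.random.default_rng([cfg.seed, 1, zlib.crc32(profile.name.encode())])

    feature_ids = np.array([f"FEAT{i:06d}" for i in range(n)])
    n_genes = max(1, int(round(n * 0.85)))
    gene_idx = np.concatenate(
        [np.arange(n_genes), prng.integers(0, n_genes, size=n - n_genes)]
    )
    prng.shuffle(gene_idx)
    gene_ids = np.array([f"G{gi:06d}" for gi in gene_idx])

    gc = np.clip(prng.normal(45.0, 8.0, n), 20.0, 80.0)
    length = np.rint(np.clip(prng.normal(500.0, 60.0, n), 150.0, 900.0)).astype(int)
    gene2go = _annotate_genes(sorted(set(gene_ids)), prng)
    go_terms = np.array([";".join(gene2go.get(g, ())) for g in gene_ids])

    pct_id = _sample_mixture(profile, n, srng)
    no_hit = srng.random(n) < profile.frac_missing_ortholog

    deep_mask = np.isin(gene_ids, list(deep_genes))
    if deep_mask.any():
        pct_id[deep_mask] = deep_pct_id + srng.uniform(-2.0, 2.0, deep_mask.sum())
        no_hit[deep_mask] = False

    # conserved anchors: the most conserved hit features, forced to >= 95 %ID
    eligible = np.flatnonzero(~no_hit & ~deep_mask)
    order = eligible[np.argsort(pct_id[eligible])[::-1]]
    conserved_idx = order[: cfg.conserved_n]
    low = conserved_idx[pct_id[conserved_idx] < 95.0]
    if low.size:
        a, b = (95.0 - 97.5) / 1.5, (100.0 - 97.5) / 1.5
        pct_id[low] = stats.truncnorm.rvs(a, b, loc=97.5, scale=1.5, size=low.size, random_state=srng)
    conserved = np.zeros(n, dtype=bool)
    conserved[conserved_idx] = True

    sim_id = np.where(no_hit, NO_HIT_FLOOR_ID, pct_id)
    pct_align = 100.0 - 1.2 * (100.0 - sim_id) + srng.normal(0.0, 6.0, n)
    pct_align = np.clip(pct_align, 5.0, None)

    def z(x):
        return (x - x.mean()) / x.std(ddof=0)

    z_id, z_gc, z_align = z(sim_id), z(gc), z(pct_align)
    mu_det = cfg.beta0 + cfg.beta_id * sim_id
    kinetic = (
        cfg.beta_gc * z_gc
        + cfg.beta_align * z_align
        + cfg.beta_id_gc * z_id * z_gc
        + srng.normal(0.0, 1.0, n) * np.asarray(cfg.sd_kinetic(sim_id))
    )

    annotations = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "gene_id": gene_ids,
            "probe_length_bp": length,
            "gc_percent": gc,
            "conserved": conserved.astype(int),
            "true_pct_id": np.where(no_hit, np.nan, pct_id),
            "pct_align": np.where(no_hit, np.nan, pct_align),
            "no_hit": no_hit,
            "go_terms": go_terms,
        }
    )
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "gene_id": gene_ids,
            "true_pct_id": sim_id,
            "pct_align": pct_align,
            "gc_percent": gc,
            "probe_length_bp": length,
            "kinetic_dev": kinetic,
            "true_mean_m": mu_det + kinetic,
            "conserved": conserved.astype(int),
            "no_hit": no_hit,
            "go_terms": go_terms,
        }
    )
    return annotations, truth


def simulate_scans(
    annotations: pd.DataFrame, truth: pd.DataFrame, cfg: GeneratorConfig, stream: int = 0
) -> list[ArrayScan]:
    """Simulate two-channel scans for ``cfg.n_arrays`` dye-swapped arrays.

    Odd-indexed arrays carry the swapped dye orientation.  A fraction
    ``frac_lowquality`` of observations has foreground forced below the
    background + 2 SD quality threshold.  ``stream`` decorrelates the noise
    of independent hybridization experiments sharing one config.
    """
    if not np.array_equal(annotations["feature_id"].values, truth["feature_id"].values):
        raise ConfigurationError("annotations and truth are not aligned by feature id")
    n = len(truth)
    rng = np.random.default_rng([cfg.seed, 2, stream])
    mu = truth["true_mean_m"].to_numpy()
    sd_tech = np.asarray(cfg.sd_technical(truth["true_pct_id"].to_numpy()), dtype=float)

    scans = []
    for a in range(cfg.n_arrays):
        swapped = a % 2 == 1
        sign = -1.0 if swapped else 1.0
        A = rng.normal(12.0, 1.0, n)
        eps = rng.normal(0.0, 1.0, n) * sd_tech
        t = np.clip((A - 12.0) / 2.0, -1.5, 1.5)
        trend = cfg.intensity_trend_amplitude * t**3
        m_raw = sign * (mu + eps) + cfg.dye_bias + trend
        sig635 = 2.0 ** (A + m_raw / 2.0)
        sig532 = 2.0 ** (A - m_raw / 2.0)
        b635 = np.clip(rng.normal(cfg.background_mean, cfg.background_sd, n), 1.0, None)
        b532 = np.clip(rng.normal(cfg.background_mean, cfg.background_sd, n), 1.0, None)
        f635 = sig635 + b635
        f532 = sig532 + b532
        lowq = rng.random(n) < cfg.frac_lowquality
        if lowq.any():
            k = int(lowq.sum())
            f635[lowq] = b635[lowq] + rng.uniform(0.0, 1.5, k) * cfg.background_sd
            f532[lowq] = b532[lowq] + rng.uniform(0.0, 1.5, k) * cfg.background_sd
        data = pd.DataFrame(
            {
                "F635": f635,
                "B635": b635,
                "F532": f532,
                "B532": b532,
                "flag": np.zeros(n, dtype=int),
            },
            index=pd.Index(truth["feature_id"], name="feature_id"),
        )
        scans.append(ArrayScan(array_id=f"array_{a:02d}", dye_swapped=swapped, data=data))
    return scans


# --------------------------------------------------------------------------
# dataset I/O

def _annotation_out(annotations: pd.DataFrame) -> pd.DataFrame:
    out = annotations.copy()
    out["true_pct_id"] = [
        NO_HIT if nh else repr(float(v))
        for nh, v in zip(out["no_hit"], annotations["true_pct_id"])
    ]
    out["pct_align"] = [
        NO_HIT if nh else repr(float(v))
        for nh, v in zip(out["no_hit"], annotations["pct_align"])
    ]
    return out.drop(columns=["no_hit"])


def write_dataset(
    scans: list[ArrayScan],
    annotations: pd.DataFrame,
    truth: pd.DataFrame,
    dir_path: str | Path,
    cfg: GeneratorConfig | None = None,
) -> dict:
    """Write scans (GPR-like TSV), annotation, truth, GO tables and a manifest.

    Re-reading the files reproduces all numeric values bit-exactly; the
    manifest records the seed so the dataset can be regenerated.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scan_files = []
    for scan in scans:
        fname = f"{scan.array_id}.tsv"
        with open(dir_path / fname, "w") as fh:
            fh.write(f"# array_id: {scan.array_id}\n")
            fh.write(f"# dye_swapped: {str(scan.dye_swapped).lower()}\n")
            fh.write("\t".join(SCAN_COLUMNS) + "\n")
            for fid, row in zip(scan.data.index, scan.data.itertuples(index=False)):
                fh.write(
                    f"{fid}\t{row.F635!r}\t{row.B635!r}\t{row.F532!r}\t{row.B532!r}\t{row.flag}\n"
                )
        scan_files.append(fname)

    _annotation_out(annotations).to_csv(dir_path / "annotations.tsv", sep="\t", index=False)
    truth.to_csv(dir_path / "truth.tsv", sep="\t", index=False)
    edges, names = make_go_dag()
    edges.to_csv(dir_path / "go_edges.tsv", sep="\t", index=False)
    names.to_csv(dir_path / "go_names.tsv", sep="\t", index=False)

    manifest = {
        "n_features": len(annotations),
        "n_arrays": len(scans),
        "scan_files": scan_files,
        "annotation_file": "annotations.tsv",
        "truth_file": "truth.tsv",
        "go_edges_file": "go_edges.tsv",
    }
    if cfg is not None:
        d = {k: v for k, v in vars(cfg).items() if not callable(v)}
        d["sd_kinetic"] = getattr(cfg.sd_kinetic, "__name__", "custom")
        d["sd_technical"] = getattr(cfg.sd_technical, "__name__", "custom")
        manifest["seed"] = cfg.seed
        manifest["config"] = d
    with open(dir_path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV, turning ``NoHit`` sentinels into NaN + flag."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_id": str}, float_precision="round_trip")
    no_hit = df["true_pct_id"].astype(str).eq(NO_HIT)
    df["no_hit"] = no_hit
    for col in ("true_pct_id", "pct_align"):
        df[col] = df[col].map(lambda v: np.nan if str(v) == NO_HIT else float(v))
    df["go_terms"] = df["go_terms"].fillna("")
    return df


def simulate_study(
    cfg: GeneratorConfig,
    profiles: Sequence[SpeciesProfile],
    n_deep_genes: int = 0,
    deep_pct_id: float = 65.0,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame, list[ArrayScan]]]:
    """Simulate several species contrasts on one shared platform.

    When ``n_deep_genes`` > 0, that many genes are planted as highly diverged
    (near ``deep_pct_id``) in *every* species, emulating genes with strongly
    reduced hybridization across the whole study.
    """
    ann0, _ = generate_feature_annotations(cfg, profiles[0])
    genes = sorted(set(ann0["gene_id"]))
    rng = np.random.default_rng([cfg.seed, 3])
    deep = tuple(rng.choice(genes, size=n_deep_genes, replace=False)) if n_deep_genes else ()
    out = {}
    for prof in profiles:
        ann, truth = generate_feature_annotations(cfg, prof, deep_genes=deep, deep_pct_id=deep_pct_id)
        scans = simulate_scans(ann, truth, cfg, stream=zlib.crc32(prof.name.encode()))
        out[prof.name] = (ann, truth, scans)
    return out
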
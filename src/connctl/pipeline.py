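"""End-to-end orchestration: simulate -> connectome -> controllability ->
group inference -> spatial association, as a pure function of a run
configuration.

A run is reproducible bitwise from its :class:`RunConfig`: the global seed
deterministically spawns per-stage substreams, every CSV written carries the
configuration hash in a comment header, and rerunning with the same config
produces identical payloads.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .association import AbnormalityMap, associate_all, differential_expression_by_region
from .connectome import build_connectome
from .controllability import profile_cohort
from .inference import (
    COVARIATE_COLUMNS,
    ancova_f,
    ancova_table,
    correlate_clinical,
    posthoc_pairwise,
)
from .synthetic import (
    LOADS,
    cohort_frame,
    default_ground_truth,
    generate_annotation_maps,
    generate_cohort,
    generate_expression,
    generate_parcellation,
    generate_timeseries,
)

DEFAULT_CORRELATION_VARIABLES = (
    "bprs", "ymrs", "hamd", "acc_0back", "acc_2back", "rt_2back",
)


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    # cohort / atlas
    group_sizes: dict = field(default_factory=lambda: {"SZ": 105, "BD": 67, "MDD": 51, "HC": 80})
    n_nodes: int = 264
    # ground truth
    null_effects: bool = False  # strip all injected effects (calibration runs)
    modular_radius: float = 0.35
    global_strength: float = 0.6
    severity_scale: float = 0.25
    # time series
    noise_sd: float = 1.0
    # connectome / controllability
    clip: float = 0.999999
    # inference
    alpha: float = 0.05
    posthoc_family: str = "per_node"
    correlation_variables: tuple = DEFAULT_CORRELATION_VARIABLES
    # association
    n_perm: int = 5000
    null_kind: str = "label_shuffle"
    n_maps: int = 9
    planted_rho: float = 0.6
    n_genes: int = 200
    n_de_genes: int = 20
    de_effect: float = 1.5
    min_samples: int = 5
    # output
    outdir: str = "connctl_run"
    write_timeseries: bool = False
    write_connectomes: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["correlation_variables"] = list(self.correlation_variables)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "correlation_variables" in d:
            d["correlation_variables"] = tuple(d["correlation_variables"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable summary of a completed run."""

    config_hash: str
    version: str
    n_subjects: int
    n_nodes: int
    row_counts: dict
    detected: dict  # "<metric>_<load>" -> sorted node ids
    network_tally: dict  # "<metric>_<load>" -> {network: count}
    association_significant: dict  # metric -> [map names with q < alpha]
    n_surviving_genes: dict  # metric -> count
    de_region_source: dict  # metric -> "detected" | "ground_truth"
    wall_clock_s: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def summarize_by_network(node_results, parcellation) -> pd.Series:
    """Count detected nodes per large-scale network.

    ``node_results`` is either a sequence of node ids or a frame with a
    ``node_id`` column (and optional boolean ``detected`` column, which is
    honored when present).
    """
    if isinstance(node_results, pd.DataFrame):
        df = node_results
        ids = df.loc[df["detected"], "node_id"] if "detected" in df else df["node_id"]
        ids = ids.to_numpy(int)
    else:
        ids = np.asarray(list(node_results), int)
    networks = pd.Series(parcellation.networks)
    if np.any(ids < 0) or np.any(ids >= len(networks)):
        raise ValueError("detected node outside the parcellation")
    labels = networks.iloc[ids]
    if labels.isna().any():
        raise ValueError("unlabeled node in the detected set")
    tally = labels.value_counts()
    tally.index.name = "network"
    tally.name = "n_detected"
    return tally


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# connctl {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def signed_statistic_map(values: np.ndarray, diagnosis, covariates) -> np.ndarray:
    """Signed per-node group-difference map: sign(HC - patients) * sqrt(F).

    The omnibus F quantifies the group effect; the sign marks whether the
    (covariate-adjusted) healthy-control mean exceeds the pooled patient
    mean, so deficits in patients appear as positive map values.
    """
    f, _ = ancova_f(values, diagnosis, covariates)
    diagnosis = np.asarray(diagnosis)
    cov = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    design = np.column_stack([np.ones(len(diagnosis)), cov])
    resid = values - design @ np.linalg.lstsq(design, values, rcond=None)[0]
    hc = resid[diagnosis == "HC"].mean(axis=0)
    pat = resid[diagnosis != "HC"].mean(axis=0)
    return np.sign(hc - pat) * np.sqrt(f)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute every stage and write CSV/JSON outputs under ``outdir``."""
    t0 = time.perf_counter()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    ss = np.random.SeedSequence(config.seed)
    (s_atlas, s_truth, s_cohort, s_ts, s_maps, s_expr, s_assoc) = ss.spawn(7)

    # --- stage 1: simulate -------------------------------------------------
    parcellation = generate_parcellation(config.n_nodes, seed=np.random.default_rng(s_atlas))
    truth = default_ground_truth(
        parcellation,
        seed=np.random.default_rng(s_truth),
        modular_radius=config.modular_radius,
        global_strength=config.global_strength,
        severity_scale=config.severity_scale,
    )
    if config.null_effects:
        from dataclasses import replace

        truth = replace(truth, effects=())
    cohort = generate_cohort(config.group_sizes, seed=np.random.default_rng(s_cohort))
    pheno = cohort_frame(cohort)
    parcellation.write(out / "atlas.tsv")
    with open(out / "phenotype.csv", "w") as fh:
        fh.write(f"# connctl {__version__} config_hash={chash}\n")
        pheno.to_csv(fh, index=False, na_rep="")

    # --- stage 2: connectomes ---------------------------------------------
    ts_dir = out / "timeseries"
    conn_dir = out / "connectomes"
    if config.write_timeseries:
        ts_dir.mkdir(exist_ok=True)
    if config.write_connectomes:
        conn_dir.mkdir(exist_ok=True)
    ts_seeds = s_ts.spawn(len(cohort) * len(LOADS))
    connectomes = []
    k = 0
    for subject in cohort:
        for load in LOADS:
            ts = generate_timeseries(
                subject, load, truth, noise_sd=config.noise_sd,
                seed=np.random.default_rng(ts_seeds[k]),
            )
            k += 1
            if config.write_timeseries:
                ts.write(ts_dir / f"{subject.subject_id}_{load}.txt")
            conn = build_connectome(ts, clip=config.clip)
            if config.write_connectomes:
                conn.write(conn_dir / f"{subject.subject_id}_{load}.txt")
            connectomes.append(conn)

    # --- stage 3: controllability profiles ---------------------------------
    profiles = profile_cohort(connectomes, networks=parcellation.networks)
    _write_csv(profiles, out / "profiles.csv", chash)

    # --- stage 4: nodewise inference ---------------------------------------
    diagnosis = pheno["diagnosis"].to_numpy()
    covariates = pheno[list(COVARIATE_COLUMNS)]
    subject_order = pheno["subject_id"].tolist()
    stats_tables = []
    posthoc_tables = []
    corr_tables = []
    detected: dict[str, list[int]] = {}
    tallies: dict[str, dict] = {}
    value_mats: dict[tuple[str, str], np.ndarray] = {}
    for metric in ("ac", "mc"):
        for load in LOADS:
            sub = profiles[profiles["load"] == load]
            mat = (
                sub.pivot(index="subject_id", columns="node_id", values=metric)
                .loc[subject_order]
                .to_numpy()
            )
            value_mats[(metric, load)] = mat
            table = ancova_table(mat, diagnosis, covariates, metric=metric,
                                 load=load, alpha=config.alpha)
            stats_tables.append(table)
            nodes = table.loc[table["detected"], "node_id"].tolist()
            detected[f"{metric}_{load}"] = nodes
            tallies[f"{metric}_{load}"] = summarize_by_network(nodes, parcellation).to_dict()
            ph = posthoc_pairwise(mat, diagnosis, covariates, nodes,
                                  family=config.posthoc_family)
            ph.insert(1, "metric", metric)
            ph.insert(2, "load", load)
            posthoc_tables.append(ph)
            cc = correlate_clinical(
                mat, pheno, nodes, list(config.correlation_variables),
                metric=metric, load=load,
            )
            corr_tables.append(cc)
    node_stats = pd.concat(stats_tables, ignore_index=True)
    posthoc = pd.concat(
        [t for t in posthoc_tables if len(t)] or posthoc_tables[:1], ignore_index=True
    )
    correlations = pd.concat(
        [t for t in corr_tables if len(t)] or corr_tables[:1], ignore_index=True
    )
    _write_csv(node_stats, out / "node_stats.csv", chash)
    _write_csv(posthoc, out / "posthoc.csv", chash)
    _write_csv(correlations, out / "correlations.csv", chash)

    # --- stage 5: spatial association ---------------------------------------
    # ground-truth deficit pattern under high load, used to plant one
    # recoverable annotation map
    assoc_tables = []
    assoc_sig: dict[str, list[str]] = {}
    n_surv: dict[str, int] = {}
    de_source: dict[str, str] = {}
    expr_region_truth = truth.affected_nodes("mc", "2back")
    rng_maps = np.random.default_rng(s_maps)
    rng_assoc = np.random.default_rng(s_assoc)
    for metric in ("ac", "mc"):
        load = "2back"
        mat = value_mats[(metric, load)]
        signed = signed_statistic_map(mat, diagnosis, covariates)
        mask = np.zeros(config.n_nodes, bool)
        mask[detected[f"{metric}_{load}"]] = True
        abnormality = AbnormalityMap(values=signed, mask=mask)

        maps = generate_annotation_maps(
            parcellation, n_maps=config.n_maps, seed=rng_maps,
        )
        if config.planted_rho and signed.std() > 0 and config.n_maps > 0:
            planted = generate_annotation_maps(
                parcellation, n_maps=1, target_pattern=signed,
                rho=config.planted_rho, seed=rng_maps,
            )[0]
            maps[0] = type(planted)(name=maps[0].name, values=planted.values,
                                    meta=maps[0].meta + " (planted)")
        assoc = associate_all(
            abnormality, maps, n_perm=config.n_perm, null_kind=config.null_kind,
            seed=rng_assoc, coords=parcellation.coords,
        )
        assoc.insert(0, "metric", metric)
        assoc.insert(1, "load", load)
        assoc_tables.append(assoc)
        assoc_sig[metric] = assoc.loc[assoc["q"] < config.alpha, "map"].tolist()

        # regional differential expression against the detected region; fall
        # back to the ground-truth region when detection is too small or so
        # widespread that no meaningful background remains
        region = np.asarray(detected[f"{metric}_{load}"], int)
        if config.min_samples <= len(region) <= config.n_nodes - config.min_samples:
            de_source[metric] = "detected"
        else:
            region = expr_region_truth
            de_source[metric] = "ground_truth"
        if len(region) >= config.min_samples and config.n_genes > 0:
            de_spec = []
            if config.n_de_genes > 0:
                de_spec.append(
                    (np.arange(min(config.n_de_genes, config.n_genes)),
                     expr_region_truth, config.de_effect)
                )
            expr = generate_expression(
                parcellation, n_genes=config.n_genes, de_spec=de_spec,
                seed=np.random.default_rng(s_expr),
            )
            de_table, surviving = differential_expression_by_region(
                expr, region, n_perm=config.n_perm,
                min_samples=config.min_samples, seed=rng_assoc,
                alpha=config.alpha,
            )
            de_table.insert(0, "metric", metric)
            _write_csv(de_table, out / f"de_genes_{metric}.csv", chash)
            n_surv[metric] = len(surviving)
        else:
            n_surv[metric] = 0
    associations = pd.concat(assoc_tables, ignore_index=True)
    _write_csv(associations, out / "associations.csv", chash)

    # --- report --------------------------------------------------------------
    report = RunReport(
        config_hash=chash,
        version=__version__,
        n_subjects=len(cohort),
        n_nodes=config.n_nodes,
        row_counts={
            "phenotype": len(pheno),
            "profiles": len(profiles),
            "node_stats": len(node_stats),
            "posthoc": len(posthoc),
            "correlations": len(correlations),
            "associations": len(associations),
        },
        detected={k: [int(i) for i in v] for k, v in detected.items()},
        network_tally={k: {str(n): int(c) for n, c in v.items()} for k, v in tallies.items()},
        association_significant=assoc_sig,
        n_surviving_genes=n_surv,
        de_region_source=de_source,
        wall_clock_s=round(time.perf_counter() - t0, 3),
    )
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    (out / "report.json").write_text(report.to_json())
    return report


__all__ = [
    "DEFAULT_CORRELATION_VARIABLES",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "signed_statistic_map",
    "summarize_by_network",
]
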
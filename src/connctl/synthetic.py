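"""Synthetic study generator with known ground truth.

Everything downstream of image preprocessing is exercised on data produced
here: a modular parcellation with spatially clustered nodes, a four-group
cohort whose covariate and clinical-score distributions follow the published
group summaries, blocked task time series driven by stable first-order
linear dynamics with group-specific coupling perturbations, spatially
autocorrelated annotation maps, and a nodes-by-genes expression matrix with
planted regional effects.

The generators are pure functions of their configuration and seed.  The
dynamical ground truth is chosen so that the controllability metrics applied
to the generating coupling matrices themselves reproduce the intended group
ordering (graded frontoparietal modal-controllability deficit, worst in
schizophrenia), which makes every downstream inference stage testable for
recovery of a known effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("SZ", "BD", "MDD", "HC")
PATIENT_GROUPS = ("SZ", "BD", "MDD")
LOADS = ("0back", "2back")

#: Node counts per large-scale network in a widely used 264-node functional
#: parcellation; used (as proportions) as the default network composition.
POWER_NETWORK_SIZES: dict[str, int] = {
    "SMN": 35,
    "CON": 14,
    "AN": 13,
    "DMN": 58,
    "MRN": 5,
    "VN": 31,
    "FPN": 25,
    "SN": 18,
    "subcortical": 13,
    "VAN": 9,
    "DAN": 11,
    "cerebellum": 4,
    "uncertain": 28,
}

#: Nine tracer families used to name default annotation maps.
TRACER_FAMILIES = (
    "dopamine",
    "serotonin",
    "glutamate",
    "GABA",
    "acetylcholine",
    "opioid",
    "cannabinoid",
    "noradrenaline",
    "fluorodopa",
)

# Group-level covariate and score distributions: mean, SD, truncation range.
# Demographics, clinical scales and task performance follow the published
# four-group summary table; head motion (mean framewise displacement, mm) is
# not reported there and uses plausible values with patients > controls.
_T = dict  # alias for brevity in the literal below

COHORT_SUMMARY_DEFAULTS: dict = {
    "group_sizes": {"SZ": 105, "BD": 67, "MDD": 51, "HC": 80},
    "male_fraction": {"SZ": 63 / 105, "BD": 30 / 67, "MDD": 28 / 51, "HC": 39 / 80},
    "continuous": {
        # name -> {group: (mean, sd)}, plus bounds and availability
        "age": _T(params={"SZ": (25.32, 5.59), "BD": (26.19, 5.65),
                          "MDD": (29.45, 8.12), "HC": (23.23, 4.30)},
                  bounds=(18.0, 50.0), groups=GROUPS),
        "education": _T(params={"SZ": (11.87, 2.74), "BD": (13.31, 2.79),
                                "MDD": (12.14, 3.07), "HC": (13.95, 2.56)},
                        bounds=(9.0, 22.0), groups=GROUPS),
        "head_motion": _T(params={"SZ": (0.18, 0.09), "BD": (0.16, 0.08),
                                  "MDD": (0.15, 0.08), "HC": (0.12, 0.05)},
                          bounds=(0.02, 0.60), groups=GROUPS),
        "illness_duration": _T(params={"SZ": (28.25, 32.01), "BD": (52.32, 51.45),
                                       "MDD": (47.56, 58.76)},
                               bounds=(1.0, 360.0), groups=PATIENT_GROUPS),
        "cpz": _T(params={"SZ": (410.10, 211.32), "BD": (227.98, 247.02),
                          "MDD": (54.72, 150.31)},
                  bounds=(0.0, 1500.0), groups=PATIENT_GROUPS),
        "flu": _T(params={"SZ": (0.80, 4.06), "BD": (9.97, 14.45),
                          "MDD": (23.63, 18.25)},
                  bounds=(0.0, 80.0), groups=PATIENT_GROUPS),
        "sans": _T(params={"SZ": (36.57, 28.54)}, bounds=(0.0, 120.0), groups=("SZ",)),
        "saps": _T(params={"SZ": (20.86, 15.41)}, bounds=(0.0, 170.0), groups=("SZ",)),
        "bprs": _T(params={"SZ": (37.97, 11.30), "BD": (26.78, 7.69),
                           "MDD": (28.69, 5.78)},
                   bounds=(18.0, 126.0), groups=PATIENT_GROUPS),
        "ymrs": _T(params={"BD": (6.57, 8.78), "MDD": (2.35, 2.74)},
                   bounds=(0.0, 60.0), groups=("BD", "MDD")),
        "hamd": _T(params={"BD": (12.78, 9.61), "MDD": (19.41, 6.38)},
                   bounds=(0.0, 52.0), groups=("BD", "MDD")),
        "hama": _T(params={"BD": (9.97, 9.33), "MDD": (15.55, 8.51)},
                   bounds=(0.0, 56.0), groups=("BD", "MDD")),
        "acc_0back": _T(params={"SZ": (0.73, 0.28), "BD": (0.88, 0.15),
                                "MDD": (0.90, 0.15), "HC": (0.92, 0.14)},
                        bounds=(0.0, 1.0), groups=GROUPS),
        "rt_0back": _T(params={"SZ": (559.18, 151.85), "BD": (531.23, 97.95),
                               "MDD": (540.39, 133.38), "HC": (481.85, 90.59)},
                       bounds=(150.0, 2000.0), groups=GROUPS),
        "acc_2back": _T(params={"SZ": (0.49, 0.25), "BD": (0.60, 0.27),
                                "MDD": (0.62, 0.23), "HC": (0.74, 0.18)},
                        bounds=(0.0, 1.0), groups=GROUPS),
        "rt_2back": _T(params={"SZ": (701.51, 173.90), "BD": (738.57, 173.76),
                               "MDD": (716.44, 225.60), "HC": (642.04, 139.57)},
                       bounds=(150.0, 2000.0), groups=GROUPS),
    },
    # Gaussian-copula links between the latent illness severity of a subject
    # and selected scores (rank-matched within group): symptom burden rises
    # and task accuracy falls with severity.
    "score_link": {"bprs": 0.5, "acc_0back": -0.4, "acc_2back": -0.4},
}

CLINICAL_COLUMNS = (
    "illness_duration", "cpz", "flu", "sans", "saps", "bprs",
    "ymrs", "hamd", "hama",
)
PERFORMANCE_COLUMNS = ("acc_0back", "rt_0back", "acc_2back", "rt_2back")

N_BLOCKS = 4
VOLUMES_PER_BLOCK = 20


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Parcellation:
    """A node set with 3-D coordinates (mm) and network labels."""

    coords: np.ndarray  # (n_nodes, 3)
    networks: np.ndarray  # (n_nodes,) str

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, float)
        networks = np.asarray(self.networks)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_nodes, 3)")
        if len(networks) != len(coords):
            raise ValueError("networks and coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "networks", networks)

    @property
    def n_nodes(self) -> int:
        return len(self.networks)

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def nodes_in(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.networks == network)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "network": self.networks,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("node_id").reset_index(drop=True)
        if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
            raise ValueError("node_ids must be unique and contiguous from 0")
        return cls(df[["x", "y", "z"]].to_numpy(float), df["network"].to_numpy())


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: diagnosis, covariates, scores, latent severity."""

    subject_id: str
    diagnosis: str
    age: float
    sex: int  # 1 = male, 0 = female
    education: float
    head_motion: float
    clinical: dict = field(default_factory=dict)
    performance: dict = field(default_factory=dict)
    severity: float = 0.0  # latent illness severity (z score), drives coupling

    def __post_init__(self) -> None:
        if self.diagnosis not in GROUPS:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        for key in ("acc_0back", "acc_2back"):
            v = self.performance.get(key)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1]")
        for key in ("rt_0back", "rt_2back"):
            v = self.performance.get(key)
            if v is not None and v <= 0:
                raise ValueError(f"{key} must be positive")


@dataclass(frozen=True)
class GroundTruthEffect:
    """A coupling perturbation applied to one node set for some groups.

    ``gain > 1`` redistributes the dominant coherent mode's loading toward
    the nodes (lowering their modal controllability); ``gain < 1`` weakens
    the nodes' coupling overall (lowering their average controllability).
    """

    name: str
    nodes: np.ndarray
    load: str
    gains: Mapping[str, float]  # group -> multiplicative node gain

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, int)
        object.__setattr__(self, "nodes", nodes)
        if self.load not in LOADS:
            raise ValueError(f"unknown load {self.load!r}")
        for g, v in self.gains.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if not math.isfinite(v) or v <= 0:
                raise ValueError("gains must be finite and positive")


@dataclass(frozen=True)
class GroundTruth:
    """Generating coupling model: modular template plus a global coherent mode.

    A subject's coupling is ``A = M + g g' (zero diagonal)``: ``M`` a
    modular (within-network-dominant) symmetric matrix and ``g`` the node
    loadings of a dominant global mode.  Group effects perturb ``g``:

    * modal-controllability deficits *redistribute* loading toward the
      affected nodes at conserved total norm ``||g||``, so the overall
      coupling strength (and hence the downstream normalization) stays
      group-stable while the affected nodes participate more strongly in
      the weakly damped global mode;
    * average-controllability deficits attenuate both the nodes' loading
      and their modular rows — an overall disconnection.
    """

    modular_coupling: np.ndarray  # (N, N) symmetric, zero diagonal
    global_loading: np.ndarray  # (N,) nonnegative
    effects: tuple[GroundTruthEffect, ...] = ()
    severity_scale: float = 0.25  # relative modulation of effect size by severity

    def __post_init__(self) -> None:
        m = np.asarray(self.modular_coupling, float)
        g = np.asarray(self.global_loading, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("modular_coupling must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("modular_coupling must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("modular_coupling must have zero diagonal")
        if g.shape != (m.shape[0],):
            raise ValueError("global_loading must be a length-N vector")
        if np.any(g < 0) or not np.all(np.isfinite(g)):
            raise ValueError("global_loading must be finite and nonnegative")
        object.__setattr__(self, "modular_coupling", m)
        object.__setattr__(self, "global_loading", g)
        n = m.shape[0]
        for e in self.effects:
            if np.any(e.nodes < 0) or np.any(e.nodes >= n):
                raise ValueError(f"effect {e.name!r} references nodes outside the parcellation")
        rho = float(np.max(np.abs(np.linalg.eigvalsh(self.coupling("HC", LOADS[0])))))
        if rho >= 1:
            raise ValueError(f"baseline coupling spectral radius {rho:.3f} >= 1")

    @property
    def n_nodes(self) -> int:
        return self.modular_coupling.shape[0]

    @property
    def base_coupling(self) -> np.ndarray:
        """Unperturbed coupling template (shared baseline)."""
        a = self.modular_coupling + np.outer(self.global_loading, self.global_loading)
        np.fill_diagonal(a, 0.0)
        return a

    def node_gains(self, group: str, load: str, severity: float = 0.0) -> np.ndarray:
        """Per-node multiplicative gain for a subject of ``group`` under ``load``."""
        g = np.ones(self.n_nodes)
        for e in self.effects:
            if e.load != load or group not in e.gains:
                continue
            base = e.gains[group]
            # severity modulates the *deviation from 1*, keeping unaffected
            # subjects (gain 1) untouched
            dev = (base - 1.0) * (1.0 + self.severity_scale * severity)
            g[e.nodes] *= max(1.0 + dev, 0.05)
        return g

    def coupling(self, group: str, load: str, severity: float = 0.0) -> np.ndarray:
        """Coupling matrix A for a subject; symmetric with zero diagonal."""
        gains = self.node_gains(group, load, severity)
        # boosts (> 1) act on the global-mode loading, conserving its total
        # norm; attenuations (< 1) act on the modular rows only, so a local
        # disconnection does not leak into the shared global mode
        boost = np.maximum(gains, 1.0)
        atten = np.minimum(gains, 1.0)
        loading = self.global_loading * boost
        norm0 = np.linalg.norm(self.global_loading)
        norm1 = np.linalg.norm(loading)
        if norm1 > 0 and norm0 > 0:
            loading = loading * (norm0 / norm1)  # conserve total mode strength
        # attenuation is a local disconnection acting on the modular rows
        # only: touching the shared global mode would leak a cortex-wide
        # shift through the downstream 1/(1 + sigma_max) normalization
        modular = self.modular_coupling
        if np.any(atten < 1.0):
            modular = modular * np.outer(atten, atten)
        a = modular + np.outer(loading, loading)
        np.fill_diagonal(a, 0.0)
        rho = float(np.max(np.abs(np.linalg.eigvalsh(a))))
        if rho >= 1:
            raise ValueError(
                f"coupling for {group}/{load} (severity {severity:.2f}) is unstable: "
                f"spectral radius {rho:.3f} >= 1"
            )
        return a

    def group_coupling(self, group: str, load: str) -> np.ndarray:
        """Template coupling at zero severity (the group-level ground truth)."""
        return self.coupling(group, load, severity=0.0)

    def affected_nodes(self, metric: str, load: str) -> np.ndarray:
        """Nodes carrying a deficit for ``metric`` ('ac' or 'mc') under ``load``.

        A coupling boost (gain > 1) lowers modal controllability; an
        attenuation (gain < 1) lowers average controllability.
        """
        out: list[np.ndarray] = []
        for e in self.effects:
            if e.load != load:
                continue
            devs = [v - 1.0 for v in e.gains.values()]
            if metric == "mc" and any(d > 0 for d in devs):
                out.append(e.nodes)
            if metric == "ac" and any(d < 0 for d in devs):
                out.append(e.nodes)
        if not out:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(out))


@dataclass(frozen=True)
class AnnotationMap:
    """A named per-node scalar map (e.g., a receptor availability pattern)."""

    name: str
    values: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("values must be a finite 1-D vector")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Regional expression: nodes x genes, with unique gene identifiers."""

    values: np.ndarray  # (n_nodes, n_genes)
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (nodes x genes)")
        if v.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match the number of columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.gene_ids))
        df.insert(0, "node_id", np.arange(self.values.shape[0]))
        return df


# ---------------------------------------------------------------------------
# Generators


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` following ``proportions`` (sums exactly)."""
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_parcellation(
    n_nodes: int = 264,
    network_spec: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> Parcellation:
    """Generate a modular parcellation with spatially clustered networks.

    Nodes are allocated to networks by largest-remainder rounding of the
    requested proportions (default: the composition of the 264-node
    functional atlas) and placed around network-specific spatial centers, so
    that same-network nodes cluster — a prerequisite for meaningful
    autocorrelation-preserving null maps downstream.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if network_spec is None:
        total = sum(POWER_NETWORK_SIZES.values())
        network_spec = {k: v / total for k, v in POWER_NETWORK_SIZES.items()}
    names = list(network_spec)
    props = np.array([network_spec[k] for k in names], float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"network proportions must be nonnegative and sum to 1 (got {props.sum():.12f})"
        )
    rng = np.random.default_rng(seed)
    counts = _largest_remainder(props, n_nodes)

    networks: list[str] = []
    coords: list[np.ndarray] = []
    # network centers spread on a sphere of brain-like radius; nodes
    # scattered around their center
    for name, count in zip(names, counts):
        center = rng.normal(size=3)
        center *= 60.0 / max(np.linalg.norm(center), 1e-12)
        pts = center + rng.normal(scale=14.0, size=(count, 3))
        networks.extend([name] * count)
        coords.append(pts)
    coord_arr = np.vstack(coords) if coords else np.empty((0, 3))
    return Parcellation(coord_arr, np.array(networks, dtype=object))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if sd <= 0:
        raise ValueError(f"SD must be positive (got {sd})")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    group_sizes: Mapping[str, int] | None = None,
    covariate_spec: Mapping | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SubjectRecord]:
    """Generate a four-group cohort with published-summary-like distributions.

    Continuous covariates and scores are drawn from truncated normal
    distributions per group; sex is Bernoulli with the published group male
    fraction.  A latent per-subject severity (standard normal, truncated at
    |z| <= 2.5) modulates the coupling perturbation in the time-series
    generator; scores listed in ``score_link`` are rank-matched within group
    to a noisy copy of severity so that score-controllability correlations
    are recoverable downstream.
    """
    spec = dict(COHORT_SUMMARY_DEFAULTS if covariate_spec is None else covariate_spec)
    sizes = dict(spec["group_sizes"] if group_sizes is None else group_sizes)
    for g, n in sizes.items():
        if n < 2:
            raise ValueError(f"need >= 2 subjects per group (got {n} for {g})")
    rng = np.random.default_rng(seed)

    records: list[SubjectRecord] = []
    for group in GROUPS:
        n = int(sizes[group])
        sex = (rng.random(n) < spec["male_fraction"][group]).astype(int)
        severity = _truncnorm(rng, 0.0, 1.0, -2.5, 2.5, n)
        cols: dict[str, np.ndarray] = {}
        for name, cfg in spec["continuous"].items():
            if group not in cfg["groups"]:
                continue
            mean, sd = cfg["params"][group]
            lo, hi = cfg["bounds"]
            cols[name] = _truncnorm(rng, mean, sd, lo, hi, n)
        # Gaussian-copula link: reorder linked scores so their ranks follow
        # rho * severity + sqrt(1 - rho^2) * noise
        for name, rho in spec.get("score_link", {}).items():
            if name not in cols:
                continue
            latent = rho * severity + math.sqrt(1 - rho * rho) * rng.normal(size=n)
            vals = np.sort(cols[name])
            ranks = np.argsort(np.argsort(latent))
            cols[name] = vals[ranks]
        for i in range(n):
            clinical = {k: float(cols[k][i]) for k in CLINICAL_COLUMNS if k in cols}
            perf = {k: float(cols[k][i]) for k in PERFORMANCE_COLUMNS if k in cols}
            records.append(
                SubjectRecord(
                    subject_id=f"{group}{i:03d}",
                    diagnosis=group,
                    age=float(cols["age"][i]),
                    sex=int(sex[i]),
                    education=float(cols["education"][i]),
                    head_motion=float(cols["head_motion"][i]),
                    clinical=clinical,
                    performance=perf,
                    severity=float(severity[i]),
                )
            )
    return records


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tidy phenotype table, one row per subject (missing scores -> NaN)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "diagnosis": r.diagnosis,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
            "head_motion": r.head_motion,
        }
        for k in CLINICAL_COLUMNS:
            row[k] = r.clinical.get(k, np.nan)
        for k in PERFORMANCE_COLUMNS:
            row[k] = r.performance.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def default_ground_truth(
    parcellation: Parcellation,
    seed: int | np.random.Generator = 0,
    modular_radius: float = 0.35,
    global_strength: float = 0.6,
    mc_boost: Mapping[str, float] | None = None,
    ac_atten: Mapping[str, float] | None = None,
    severity_scale: float = 0.25,
) -> GroundTruth:
    """Default generating model mirroring the study's qualitative findings.

    * Modular coupling (stronger within-network) scaled to spectral radius
      ``modular_radius``, plus a global coherent mode of squared norm
      ``global_strength`` with mildly heterogeneous nonnegative loadings.
    * Under high load (2-back), the global-mode loading is redistributed
      toward roughly half of the frontoparietal nodes, graded
      SZ > BD = MDD, which lowers their modal controllability in patients
      (worst in SZ).
    * Average-controllability deficits are overall coupling attenuations:
      visual nodes (SZ and MDD) and one frontoparietal node (SZ) under high
      load, one memory-retrieval node (SZ) under low load.
    """
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    same = parcellation.networks[:, None] == parcellation.networks[None, :]
    w = np.where(same, 1.0, 0.25) * np.abs(rng.normal(1.0, 0.3, size=(n, n)))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    rho = float(np.max(np.abs(np.linalg.eigvalsh(w))))
    base = w * (modular_radius / rho)
    loading = np.abs(rng.normal(1.0, 0.2, size=n))
    loading *= math.sqrt(global_strength) / np.linalg.norm(loading)

    if mc_boost is None:
        mc_boost = {"SZ": 3.0, "BD": 2.0, "MDD": 2.0}
    if ac_atten is None:
        ac_atten = {"SZ": 0.3, "MDD": 0.3}

    def pick(network: str, k: int) -> np.ndarray:
        nodes = parcellation.nodes_in(network)
        if len(nodes) == 0:
            return nodes
        k = min(k, len(nodes))
        return np.sort(rng.choice(nodes, size=k, replace=False))

    fpn = parcellation.nodes_in("FPN")
    n_fpn_mc = max(1, int(round(0.48 * len(fpn)))) if len(fpn) else 0
    effects: list[GroundTruthEffect] = []
    if n_fpn_mc:
        mc_nodes = np.sort(rng.choice(fpn, size=n_fpn_mc, replace=False))
        effects.append(GroundTruthEffect("fpn_mc_deficit", mc_nodes, "2back", dict(mc_boost)))
        remaining = np.setdiff1d(fpn, mc_nodes)
        if len(remaining):
            effects.append(
                GroundTruthEffect(
                    "fpn_ac_deficit",
                    remaining[:1],
                    "2back",
                    {"SZ": ac_atten.get("SZ", 0.3)},
                )
            )
    vn = pick("VN", 3)
    if len(vn):
        effects.append(GroundTruthEffect("vn_ac_deficit", vn, "2back", dict(ac_atten)))
    mrn = pick("MRN", 1)
    if len(mrn):
        effects.append(
            GroundTruthEffect("mrn_ac_deficit", mrn, "0back", {"SZ": ac_atten.get("SZ", 0.3)})
        )
    return GroundTruth(base, loading, tuple(effects), severity_scale=severity_scale)


def generate_timeseries(
    subject: SubjectRecord,
    load: str,
    truth: GroundTruth,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> "BlockTimeSeries":
    """Simulate one subject/load: 4 task blocks of 20 volumes.

    Within a block the signal follows the stable linear recursion
    ``x(t+1) = A x(t) + eps`` with ``A`` the subject's coupling matrix and
    isotropic Gaussian innovations.  Each block is initialized independently
    from the exact stationary distribution of the recursion.
    """
    from .connectome import BlockTimeSeries  # local import to avoid a cycle

    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if load not in LOADS:
        raise ValueError(f"unknown load {load!r}")
    rng = np.random.default_rng(seed)
    a = truth.coupling(subject.diagnosis, load, subject.severity)
    n = a.shape[0]
    lam, vecs = np.linalg.eigh(a)
    if np.max(np.abs(lam)) >= 1:
        raise ValueError("coupling spectral radius >= 1; stationary law undefined")
    # stationary covariance of the symmetric AR(1): sigma^2 (I - A^2)^{-1}
    stat_sd = noise_sd / np.sqrt(1.0 - lam**2)

    data = np.empty((N_BLOCKS, VOLUMES_PER_BLOCK, n))
    for b in range(N_BLOCKS):
        x = vecs @ (stat_sd * rng.normal(size=n))
        for t in range(VOLUMES_PER_BLOCK):
            data[b, t] = x
            x = a @ x + noise_sd * rng.normal(size=n)
    return BlockTimeSeries(subject_id=subject.subject_id, load=load, data=data)


def _smooth_field(coords: np.ndarray, values: np.ndarray, scale: float) -> np.ndarray:
    """Gaussian-kernel smoothing of a node vector over spatial coordinates."""
    if scale <= 0:
        return values.copy()
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2.0 * scale * scale))
    return (k @ values) / k.sum(axis=1)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def generate_annotation_maps(
    parcellation: Parcellation,
    n_maps: int = 9,
    target_pattern: np.ndarray | None = None,
    rho: float = 0.0,
    smoothing_scale: float = 15.0,
    seed: int | np.random.Generator = 0,
) -> list[AnnotationMap]:
    """Generate annotation maps with distance-decaying spatial autocorrelation.

    Each map is a Gaussian-kernel-smoothed white-noise field.  When a
    ``target_pattern`` is supplied, the smoothed field is orthogonalized
    against it and recombined so the realized in-sample Pearson correlation
    with the pattern equals ``rho`` exactly.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    target = None
    if target_pattern is not None:
        target = np.asarray(target_pattern, float)
        if target.shape != (n,):
            raise ValueError(f"target_pattern must have length {n}")
        if target.std() == 0:
            raise ValueError("target_pattern is constant; correlation undefined")
        target = _standardize(target)

    maps: list[AnnotationMap] = []
    for i in range(n_maps):
        name = TRACER_FAMILIES[i % len(TRACER_FAMILIES)]
        if i >= len(TRACER_FAMILIES):
            name = f"{name}_{i // len(TRACER_FAMILIES) + 1}"
        noise = _smooth_field(parcellation.coords, rng.normal(size=n), smoothing_scale)
        if target is None:
            values = _standardize(noise) if noise.std() else noise
        elif abs(rho) == 1.0:
            values = math.copysign(1.0, rho) * target
        else:
            resid = noise - target * (noise @ target) / (target @ target)
            if resid.std() == 0:  # pragma: no cover - degenerate fallback
                resid = rng.normal(size=n)
                resid -= target * (resid @ target) / (target @ target)
            values = rho * target + math.sqrt(1 - rho * rho) * _standardize(resid)
        maps.append(AnnotationMap(name=name, values=values, meta=f"synthetic {name} map"))
    return maps


def generate_expression(
    parcellation: Parcellation,
    n_genes: int = 200,
    de_spec: Sequence[tuple[Sequence[int], Sequence[int], float]] | None = None,
    smoothing_scale: float = 10.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> ExpressionMatrix:
    """Generate a nodes-by-genes expression matrix with planted regional shifts.

    Background expression per gene is a gene-specific baseline plus a
    spatially smoothed field plus i.i.d. noise.  ``de_spec`` is a sequence of
    ``(gene_indices, node_indices, effect)`` triples: the listed genes are
    shifted additively by ``effect`` inside the listed nodes.
    """
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    values = np.empty((n, n_genes))
    baseline = rng.normal(6.0, 1.0, size=n_genes)
    for j in range(n_genes):
        fieldj = _smooth_field(parcellation.coords, rng.normal(size=n), smoothing_scale)
        fieldj = fieldj / fieldj.std() if fieldj.std() else fieldj
        values[:, j] = baseline[j] + 0.5 * fieldj + noise_sd * rng.normal(size=n)
    if de_spec:
        for genes, nodes, effect in de_spec:
            genes = np.asarray(genes, int)
            nodes = np.asarray(nodes, int)
            if not math.isfinite(effect):
                raise ValueError("effect must be finite")
            if len(nodes) == 0 and effect != 0:
                raise ValueError("empty region with nonzero effect")
            if np.any(nodes < 0) or np.any(nodes >= n):
                raise ValueError("de_spec nodes outside the parcellation")
            values[np.ix_(nodes, genes)] += effect
    gene_ids = tuple(f"gene{j:04d}" for j in range(n_genes))
    return ExpressionMatrix(values, gene_ids)


__all__ = [
    "GROUPS",
    "PATIENT_GROUPS",
    "LOADS",
    "POWER_NETWORK_SIZES",
    "TRACER_FAMILIES",
    "COHORT_SUMMARY_DEFAULTS",
    "AnnotationMap",
    "ExpressionMatrix",
    "GroundTruth",
    "GroundTruthEffect",
    "Parcellation",
    "SubjectRecord",
    "cohort_frame",
    "default_ground_truth",
    "generate_annotation_maps",
    "generate_cohort",
    "generate_expression",
    "generate_parcellation",
    "generate_timeseries",
]
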
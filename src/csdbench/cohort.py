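"""Synthetic cohort generation.

The generator is a linear-Gaussian structural model over the gold-standard
DAG, parameterised on the standardized scale: every variable is modelled
as z-scored, each edge carries a standardized path weight, and noise
variances are solved in closed form so every node has unit variance.
Raw-scale intercepts and noise scales then follow from the target
marginal mean/SD of each variable, so the published summary table is
matched exactly in expectation.

Diagnosis is generated as a latent standardized score (``DX_star``) and
additionally delivered as a 3-class code (0 = CN, 1 = MCI, 2 = AD) by
thresholding the latent.  Discovery algorithms consume the coded column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .gold import TIME_VARYING, VISITS, build_gold_standard
from .graphs import MixedGraph
from .stats import CovarianceModel

__all__ = [
    "SemParameters",
    "CalibrationError",
    "default_parameters",
    "simulate_cross_sectional",
    "simulate_longitudinal",
    "bootstrap_resample",
    "population_covariance",
    "analysis_view",
    "analysis_covariance",
]

#: Published summary statistics the generator is calibrated against.
TABLE1_MARGINALS: dict[str, tuple[float, float]] = {
    "AGE": (74.09, 7.46),
    "EDU": (16.15, 2.71),
    "FDG": (1.22, 0.17),
    "ABETA": (986.29, 459.94),
    "PTAU": (27.67, 14.76),
}
SEX_P = 0.55
APOE4_PROBS = (0.54, 0.36, 0.10)
DX_MIX = (0.31, 0.46, 0.23)  # CN / MCI / AD


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class SemParameters:
    """Structural parameters of the generator.

    ``coefficients`` are standardized path weights keyed by gold edge
    (parent, child); ``ar_coefficients`` are the standardized visit-0 ->
    visit-24 weights per duplicated variable.  ``marginals`` holds the
    target raw (mean, SD) per variable; the latent DX is standardized.
    """

    coefficients: dict[tuple[str, str], float]
    ar_coefficients: dict[str, float]
    marginals: dict[str, tuple[float, float]]
    sex_p: float = SEX_P
    apoe4_probs: tuple[float, float, float] = APOE4_PROBS
    dx_thresholds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if abs(sum(self.apoe4_probs) - 1.0) > 1e-9:
            raise CalibrationError("APOE4 probabilities must sum to 1")
        if not self.dx_thresholds[0] < self.dx_thresholds[1]:
            raise CalibrationError("dx_thresholds must be strictly increasing")
        if not 0 < self.sex_p < 1:
            raise CalibrationError("sex_p must lie in (0, 1)")

    # Raw-scale helpers (cross-sectional design by default) -------------
    def noise_scales(self, design: str = "cross_sectional") -> dict[str, float]:
        cal = _calibrate(self, design)
        return {v: cal.sd[v] * np.sqrt(cal.noise_var[v])
                for v in cal.order if cal.parents[v]}

    def intercepts(self, design: str = "cross_sectional") -> dict[str, float]:
        cal = _calibrate(self, design)
        out = {}
        for v in cal.order:
            if not cal.parents[v]:
                continue
            out[v] = cal.mean[v] - sum(
                coef * cal.sd[v] / cal.sd[p] * cal.mean[p]
                for p, coef in cal.parents[v].items())
        return out

    # YAML round-trip ---------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "coefficients": {f"{s}->{t}": float(c)
                             for (s, t), c in sorted(self.coefficients.items())},
            "ar_coefficients": {k: float(v)
                                for k, v in sorted(self.ar_coefficients.items())},
            "marginals": {k: [float(m), float(s)]
                          for k, (m, s) in sorted(self.marginals.items())},
            "sex_p": float(self.sex_p),
            "apoe4_probs": [float(p) for p in self.apoe4_probs],
            "dx_thresholds": [float(t) for t in self.dx_thresholds],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SemParameters":
        doc = yaml.safe_load(text)
        coeffs = {}
        for key, c in doc["coefficients"].items():
            s, t = key.split("->")
            coeffs[(s, t)] = float(c)
        return cls(
            coefficients=coeffs,
            ar_coefficients={k: float(v) for k, v in doc["ar_coefficients"].items()},
            marginals={k: (float(m), float(s)) for k, (m, s) in doc["marginals"].items()},
            sex_p=float(doc.get("sex_p", SEX_P)),
            apoe4_probs=tuple(doc.get("apoe4_probs", APOE4_PROBS)),
            dx_thresholds=tuple(doc["dx_thresholds"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "SemParameters":
        return cls.from_yaml(Path(path).read_text())


def default_parameters() -> SemParameters:
    """Moderate standardized effects, signs fixed by the biomarker cascade
    (lower amyloid -> more tau, less metabolism, worse diagnosis)."""
    coefficients = {
        ("AGE", "ABETA"): -0.28,
        ("APOE4", "ABETA"): -0.38,
        ("ABETA", "PTAU"): -0.45,
        ("ABETA", "FDG"): 0.35,
        ("PTAU", "FDG"): -0.35,
        ("PTAU", "DX"): 0.40,
        ("FDG", "DX"): -0.40,
        ("EDU", "DX"): -0.20,
    }
    ar = {v: 0.30 for v in TIME_VARYING}
    marginals = dict(TABLE1_MARGINALS)
    marginals["DX"] = (0.0, 1.0)  # latent scale
    p_cn, p_mci, _ = DX_MIX
    thresholds = (float(sps.norm.ppf(p_cn)), float(sps.norm.ppf(p_cn + p_mci)))
    params = SemParameters(
        coefficients=coefficients,
        ar_coefficients=ar,
        marginals=marginals,
        dx_thresholds=thresholds,
    )
    _calibrate(params, "cross_sectional")  # fail fast if infeasible
    _calibrate(params, "longitudinal")
    return params


# ---------------------------------------------------------------------------
# Closed-form calibration on the standardized scale
# ---------------------------------------------------------------------------

@dataclass
class _Calibration:
    order: list[str]
    parents: dict[str, dict[str, float]]  # node -> {parent: std coefficient}
    corr: np.ndarray                      # correlation matrix in `order`
    noise_var: dict[str, float]           # standardized residual variance
    mean: dict[str, float]
    sd: dict[str, float]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.order)}


def _base_name(node: str) -> str:
    return node.split(".")[0]


def _topological_order(g: MixedGraph) -> list[str]:
    order, placed = [], set()
    pending = list(g.nodes)
    while pending:
        for v in pending:
            if g.parents(v) <= placed:
                order.append(v)
                placed.add(v)
                pending.remove(v)
                break
        else:  # pragma: no cover - gold graphs are acyclic
            raise CalibrationError("cyclic structure")
    return order


def _exogenous_moments(params: SemParameters) -> dict[str, tuple[float, float]]:
    p = params.sex_p
    probs = np.asarray(params.apoe4_probs)
    mean_a = float(probs @ [0, 1, 2])
    var_a = float(probs @ [0, 1, 4] - mean_a**2)
    return {"SEX": (p, float(np.sqrt(p * (1 - p)))),
            "APOE4": (mean_a, float(np.sqrt(var_a)))}


def _calibrate(params: SemParameters, design: str) -> _Calibration:
    graph = build_gold_standard(design)
    order = _topological_order(graph)
    k = len(order)

    mean, sd = {}, {}
    exo = _exogenous_moments(params)
    for v in order:
        base = _base_name(v)
        if base in exo:
            mean[v], sd[v] = exo[base]
        else:
            mean[v], sd[v] = params.marginals[base]

    parents: dict[str, dict[str, float]] = {}
    for v in order:
        pmap = {}
        for p in sorted(graph.parents(v)):
            if _base_name(p) == _base_name(v):
                pmap[p] = params.ar_coefficients[_base_name(v)]
            else:
                pmap[p] = params.coefficients[(_base_name(p), _base_name(v))]
        parents[v] = pmap

    corr = np.eye(k)
    noise_var: dict[str, float] = {}
    idx = {v: i for i, v in enumerate(order)}
    for v in order:
        i = idx[v]
        pmap = parents[v]
        if not pmap:
            noise_var[v] = 1.0
            continue
        pnames = list(pmap)
        pidx = [idx[p] for p in pnames]
        beta = np.array([pmap[p] for p in pnames])
        explained = float(beta @ corr[np.ix_(pidx, pidx)] @ beta)
        nv = 1.0 - explained
        if nv <= 1e-6:
            raise CalibrationError(
                f"infeasible calibration: parents of {v} explain variance "
                f"{explained:.3f} >= 1; reduce path or AR coefficients")
        noise_var[v] = nv
        for u in order[:i]:
            corr[i, idx[u]] = corr[idx[u], i] = float(
                beta @ corr[pidx, idx[u]])
    return _Calibration(order, parents, corr, noise_var, mean, sd)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample(params: SemParameters, design: str, n: int, seed: int) -> pd.DataFrame:
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    cal = _calibrate(params, design)
    rng = np.random.default_rng(seed)
    exo = _exogenous_moments(params)

    z: dict[str, np.ndarray] = {}
    raw: dict[str, np.ndarray] = {}
    for v in cal.order:
        base = _base_name(v)
        pmap = cal.parents[v]
        if not pmap:
            if base == "SEX":
                x = (rng.random(n) < params.sex_p).astype(float)
                m, s = exo["SEX"]
            elif base == "APOE4":
                x = rng.choice([0.0, 1.0, 2.0], size=n, p=params.apoe4_probs)
                m, s = exo["APOE4"]
            else:
                m, s = cal.mean[v], cal.sd[v]
                x = m + s * rng.standard_normal(n)
            z[v] = (x - m) / s
            raw[v] = x
        else:
            zz = np.zeros(n)
            for p, coef in pmap.items():
                zz += coef * z[p]
            zz += np.sqrt(cal.noise_var[v]) * rng.standard_normal(n)
            z[v] = zz
            raw[v] = cal.mean[v] + cal.sd[v] * zz

    cols: dict[str, np.ndarray] = {}
    for v in cal.order:
        if _base_name(v) == "DX":
            t1, t2 = params.dx_thresholds
            star = z[v]
            suffix = v[2:]  # '' or '.0' / '.24'
            cols[f"DX_star{suffix}"] = star
            cols[f"DX{suffix}"] = np.digitize(star, [t1, t2]).astype(float)
        else:
            cols[v] = raw[v]
    return pd.DataFrame(cols)


def simulate_cross_sectional(params: SemParameters, n: int = 1008,
                             seed: int = 0) -> pd.DataFrame:
    """Sample a baseline-only cohort (default n matches the analyzable
    baseline sample size, 1008)."""
    return _sample(params, "cross_sectional", n, seed)


def simulate_longitudinal(params: SemParameters, n: int = 266,
                          seed: int = 0) -> pd.DataFrame:
    """Sample a two-visit cohort (default n matches the regular two-year
    follow-up subsample, 266)."""
    return _sample(params, "longitudinal", n, seed)


def bootstrap_resample(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Participant-level resample with replacement, same size."""
    if len(cohort) == 0:
        raise ValueError("cannot resample an empty cohort")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cohort), size=len(cohort))
    return cohort.iloc[idx].reset_index(drop=True)


def analysis_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """Columns as consumed by the discovery algorithms: latent DX columns
    dropped, coded DX kept as a numeric column."""
    keep = [c for c in cohort.columns if not c.startswith("DX_star")]
    return cohort[keep]


def analysis_covariance(cohort: pd.DataFrame) -> CovarianceModel:
    return CovarianceModel.from_dataframe(analysis_view(cohort))


def population_covariance(params: SemParameters, design: str = "cross_sectional",
                          n: int = 1008) -> CovarianceModel:
    """Exact model-implied covariance (latent DX scale, raw units), with a
    pseudo sample size ``n`` attached for scoring."""
    cal = _calibrate(params, design)
    d = np.array([cal.sd[v] for v in cal.order])
    cov = cal.corr * np.outer(d, d)
    return CovarianceModel(tuple(cal.order), cov, n)
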
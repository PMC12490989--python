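"""Synthetic cohort generation with a known partial-correlation structure.

The generator emulates the study population the analysis assumes: two
strata (132 metabolically healthy and 56 metabolically unhealthy
overweight/obese young adults by default), each drawn from a latent
multivariate normal whose correlation matrix is induced from a **target
partial-correlation matrix**, so that the estimation pipeline has a known
ground truth to recover.  Per stratum:

1. latent draws Z ~ N(0, Sigma) with Sigma = ``partials_to_correlation``
   of the target Rp;
2. continuous nodes are rescaled to the stratum's published means/SDs;
3. the dichotomous hypertension flag is obtained by thresholding its
   latent coordinate at the quantile matching the target prevalence
   (tetrachoric-style, so HTN keeps coherent latent correlations);
4. fasting insulin is minimally re-targeted on any record whose computed
   HOMA-IR (glucose x insulin / 405) falls on the wrong side of the
   cut-off of 3, making stratum membership a hard guarantee rather than
   a statistical one.

The default moments reproduce the published descriptive table of the
cohort being emulated.  That table is internally inconsistent — its
glucose and insulin means cannot yield its printed HOMA-IR means under
the HOMA formula — so the HOMA node column is drawn at the printed HOMA
moments while stratum membership is driven by the recomputed value; the
stratifier surfaces exactly this supplied-vs-recomputed discrepancy.

Everything is deterministic given the master seed; per-stratum and
per-replicate streams are derived via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, GenerationError
from .io import CohortTable
from .network import PartialCorrelationNetwork
from .schema import DEFAULT_SCHEMA, NODES, NodeSchema
from .stratify import HOMA_IR_THRESHOLD, MHO, MUO, compute_homa_ir, stratify_cohort

#: Continuous nodes (everything except the binary HTN flag).
CONTINUOUS_NODES = tuple(n for n in NODES if n != "HTN")

#: Default per-stratum means of the continuous nodes (glucose mg/dL,
#: insulin mU/L; cholesterol/TAG in the units supplied by the source
#: table, carried opaquely).
DEFAULT_MEANS = {
    MHO: {
        "BMI": 27.63, "Glucose": 139.03, "Insulin": 2.16, "CholesT": 5.74,
        "TAG": 5.08, "HOMA": 10.46, "Depre": 94.29, "Anxiety": 9.34,
        "Stress": 179.67, "NP1": 7249.85, "NP2": 271.83, "NP3": 76.63,
    },
    MUO: {
        "BMI": 30.10, "Glucose": 168.46, "Insulin": 3.44, "CholesT": 6.23,
        "TAG": 5.54, "HOMA": 11.23, "Depre": 109.72, "Anxiety": 12.90,
        "Stress": 225.40, "NP1": 6634.49, "NP2": 270.28, "NP3": 78.05,
    },
}

#: Default per-stratum standard deviations.
DEFAULT_SDS = {
    MHO: {
        "BMI": 2.28, "Glucose": 49.56, "Insulin": 0.55, "CholesT": 1.27,
        "TAG": 1.54, "HOMA": 2.60, "Depre": 5.45, "Anxiety": 2.42,
        "Stress": 39.20, "NP1": 1905.83, "NP2": 45.21, "NP3": 18.49,
    },
    MUO: {
        "BMI": 3.56, "Glucose": 53.62, "Insulin": 0.44, "CholesT": 1.31,
        "TAG": 1.54, "HOMA": 2.61, "Depre": 13.61, "Anxiety": 2.47,
        "Stress": 63.85, "NP1": 1772.06, "NP2": 46.44, "NP3": 18.16,
    },
}

#: Default hypertension prevalence per stratum (19/132 and 29/56).
DEFAULT_HTN_PREVALENCE = {MHO: 0.144, MUO: 0.518}

#: Lower truncation per node: BMI respects study eligibility (>= 25),
#: concentrations stay strictly positive, questionnaire scores stay
#: non-negative; NP factor scores are unrestricted reals.
_FLOORS = {
    "BMI": 25.0, "Glucose": 10.0, "Insulin": 0.05, "CholesT": 0.05,
    "TAG": 0.05, "HOMA": 0.01, "Depre": 0.0, "Anxiety": 0.0, "Stress": 0.0,
}

#: Named true-network scenarios: unordered node pair -> target Rp.
#: Magnitudes are module defaults (moderate partial correlations), not
#: estimates from any dataset.
SCENARIOS: dict[str, dict[tuple[str, str], float]] = {
    # psychological triangle plus stress linked to diet and BMI
    "mho_like": {
        ("Depre", "Anxiety"): 0.40, ("Depre", "Stress"): 0.40,
        ("Anxiety", "Stress"): 0.35, ("Stress", "NP2"): 0.30,
        ("Stress", "NP3"): 0.35, ("Stress", "BMI"): 0.30,
    },
    # fat/sodium pattern as a hub wired to lipids and glycemia
    "muo_like": {
        ("NP3", "CholesT"): 0.40, ("NP3", "TAG"): 0.35,
        ("NP3", "Glucose"): 0.30, ("NP3", "HOMA"): 0.30,
        ("NP3", "NP1"): 0.30, ("NP3", "NP2"): 0.30,
        ("CholesT", "TAG"): 0.35,
    },
    # independence: used for selection-rule calibration
    "null": {},
    # six well-separated edges of |Rp| = 0.4 for recovery experiments;
    # insulin-free support (insulin is re-targeted by the HOMA guarantee)
    "recovery": {
        ("Depre", "Anxiety"): 0.40, ("Anxiety", "Stress"): 0.40,
        ("Stress", "BMI"): 0.40, ("NP3", "CholesT"): 0.40,
        ("NP3", "TAG"): 0.40, ("NP1", "NP2"): -0.40,
    },
}


def scenario_matrix(name: str, schema: NodeSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Target partial-correlation matrix for a named scenario."""
    if name not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {name!r}; expected one of {tuple(SCENARIOS)}")
    rp = np.zeros((schema.n_nodes, schema.n_nodes))
    for (u, v), w in SCENARIOS[name].items():
        i, j = schema.index(u), schema.index(v)
        rp[i, j] = rp[j, i] = w
    np.fill_diagonal(rp, 1.0)
    return rp


def partials_to_correlation(rp: np.ndarray) -> np.ndarray:
    """Correlation matrix whose partial correlations equal ``rp``.

    Builds the unit-diagonal precision matrix P with off-diagonal
    ``-rp_ij``, inverts it, and rescales to unit diagonal.  Applying the
    estimation map (:func:`~metabonet.network.compute_partial_correlations`)
    to the result recovers ``rp``.

    Raises
    ------
    GenerationError
        if the induced precision matrix is not positive definite, naming
        the largest-magnitude offending entries.
    """
    rp = np.asarray(rp, dtype=float)
    p = len(rp)
    prec = -rp.copy()
    np.fill_diagonal(prec, 1.0)
    prec = (prec + prec.T) / 2.0
    eigmin = float(np.linalg.eigvalsh(prec).min())
    if eigmin <= 1e-10:
        iu = np.triu_indices(p, k=1)
        mags = np.abs(rp[iu])
        top = np.argsort(mags)[::-1][:3]
        worst = [(int(iu[0][t]), int(iu[1][t]), float(rp[iu[0][t], iu[1][t]])) for t in top]
        raise GenerationError(
            "target partial correlations do not induce a positive-definite "
            f"precision matrix (min eigenvalue {eigmin:.3e}); largest entries: {worst}"
        )
    sigma = np.linalg.inv(prec)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class SyntheticCohortParams:
    """Full parameterisation of the synthetic cohort generator."""

    n_mho: int = 132
    n_muo: int = 56
    means: dict = field(default_factory=lambda: {s: dict(DEFAULT_MEANS[s]) for s in (MHO, MUO)})
    sds: dict = field(default_factory=lambda: {s: dict(DEFAULT_SDS[s]) for s in (MHO, MUO)})
    htn_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_HTN_PREVALENCE))
    scenario: dict = field(default_factory=lambda: {MHO: "mho_like", MUO: "muo_like"})
    true_partial_corr: dict | None = None  # stratum -> 13x13 matrix; overrides scenario
    seed: int = 0
    glucose_units: str = "mg/dL"
    schema: NodeSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        for name, n in (("n_mho", self.n_mho), ("n_muo", self.n_muo)):
            if n < 15:
                raise GenerationError(f"{name} must be >= 15 for downstream estimation, got {n}")
        for stratum in (MHO, MUO):
            for node in CONTINUOUS_NODES:
                if node not in self.means[stratum] or node not in self.sds[stratum]:
                    raise GenerationError(f"missing mean/sd for node {node!r} in stratum {stratum}")
                sd = self.sds[stratum][node]
                if not np.isfinite(sd) or sd <= 0:
                    raise GenerationError(f"sd for {node!r} in {stratum} must be > 0, got {sd}")
                if not np.isfinite(self.means[stratum][node]):
                    raise GenerationError(f"non-finite mean for {node!r} in {stratum}")
            prev = self.htn_prevalence[stratum]
            if not 0.0 < prev < 1.0:
                raise GenerationError(f"HTN prevalence in {stratum} must be in (0, 1), got {prev}")
        # resolve and PD-check the target matrices once, at construction
        resolved = {}
        for stratum in (MHO, MUO):
            if self.true_partial_corr is not None:
                rp = np.asarray(self.true_partial_corr[stratum], dtype=float)
                if rp.shape != (self.schema.n_nodes,) * 2:
                    raise GenerationError(
                        f"true partial-correlation matrix for {stratum} must be "
                        f"{self.schema.n_nodes}x{self.schema.n_nodes}"
                    )
                rp = (rp + rp.T) / 2.0
                np.fill_diagonal(rp, 1.0)
            else:
                rp = scenario_matrix(self.scenario[stratum], self.schema)
            partials_to_correlation(rp)  # raises if not PD
            resolved[stratum] = rp
        self._resolved_rp = resolved

    def target_rp(self, stratum: str) -> np.ndarray:
        return self._resolved_rp[stratum]

    def n(self, stratum: str) -> int:
        return self.n_mho if stratum == MHO else self.n_muo


@dataclass
class GroundTruth:
    """Exact generating configuration, serialised beside every cohort."""

    rp: dict                    # stratum -> 13x13 target partial correlations
    htn_threshold: dict         # stratum -> latent cut point
    seeds: dict                 # master seed and derived per-stratum seeds
    n_homa_adjusted: dict       # stratum -> records whose insulin was re-targeted
    n: dict                     # stratum -> stratum size

    def to_json_dict(self) -> dict:
        return {
            "rp": {s: np.asarray(m).tolist() for s, m in self.rp.items()},
            "htn_threshold": self.htn_threshold,
            "seeds": self.seeds,
            "n_homa_adjusted": self.n_homa_adjusted,
            "n": self.n,
            "nodes": list(NODES),
        }

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def _generate_stratum(params: SyntheticCohortParams, stratum: str,
                      seed: int) -> tuple[pd.DataFrame, dict]:
    """One stratum's node table plus its ground-truth fragment."""
    schema = params.schema
    n = params.n(stratum)
    rng = np.random.default_rng(seed)
    sigma = partials_to_correlation(params.target_rp(stratum))
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, schema.n_nodes)) @ chol.T

    df = pd.DataFrame(index=range(n))
    prev = params.htn_prevalence[stratum]
    threshold = float(stats.norm.ppf(1.0 - prev))
    for node in schema.nodes:
        col = z[:, schema.index(node)]
        if node == "HTN":
            df[node] = (col > threshold).astype(int)
        else:
            x = params.means[stratum][node] + params.sds[stratum][node] * col
            if node in _FLOORS:
                x = np.maximum(x, _FLOORS[node])
            df[node] = x

    # hard HOMA guarantee: re-target insulin on wrong-side records
    homa = compute_homa_ir(df["Glucose"], df["Insulin"], params.glucose_units)
    wrong = (homa >= HOMA_IR_THRESHOLD) if stratum == MHO else (homa < HOMA_IR_THRESHOLD)
    n_adjusted = int(wrong.sum())
    if n_adjusted:
        denom = 405.0 if params.glucose_units == "mg/dL" else 22.5
        offset = 0.05 + 0.45 * rng.uniform(size=n_adjusted)
        sign = -1.0 if stratum == MHO else 1.0
        target = HOMA_IR_THRESHOLD + sign * offset
        glucose = df.loc[wrong, "Glucose"].to_numpy()
        new_insulin = target * denom / glucose
        if np.any(~np.isfinite(new_insulin)) or np.any(new_insulin <= 0):
            raise GenerationError(
                f"HOMA re-targeting produced invalid insulin in stratum {stratum}; "
                "check glucose means/SDs"
            )
        df.loc[wrong, "Insulin"] = new_insulin
        homa = compute_homa_ir(df["Glucose"], df["Insulin"], params.glucose_units)
        still = (homa >= HOMA_IR_THRESHOLD) if stratum == MHO else (homa < HOMA_IR_THRESHOLD)
        if still.any():
            raise GenerationError(f"HOMA constraint infeasible in stratum {stratum}")
    truth = {"htn_threshold": threshold, "seed": int(seed), "n_homa_adjusted": n_adjusted}
    return df, truth


def generate_cohort(params: SyntheticCohortParams) -> tuple[CohortTable, GroundTruth]:
    """Generate the two-stratum cohort; deterministic given ``params.seed``.

    Returns the cohort table (MHO rows first, then MUO, with opaque
    subject IDs) and the ground truth used to generate it.
    """
    ss = np.random.SeedSequence(params.seed)
    stratum_seeds = {s: int(state) & 0x7FFFFFFF
                     for s, state in zip((MHO, MUO), ss.generate_state(2))}
    frames, fragments = [], {}
    for stratum in (MHO, MUO):
        df, truth = _generate_stratum(params, stratum, stratum_seeds[stratum])
        frames.append(df)
        fragments[stratum] = truth
    data = pd.concat(frames, ignore_index=True)
    data.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(data))])
    table = CohortTable(data, glucose_units=params.glucose_units, schema=params.schema)
    truth = GroundTruth(
        rp={s: params.target_rp(s) for s in (MHO, MUO)},
        htn_threshold={s: fragments[s]["htn_threshold"] for s in (MHO, MUO)},
        seeds={"master": int(params.seed),
               **{s: fragments[s]["seed"] for s in (MHO, MUO)}},
        n_homa_adjusted={s: fragments[s]["n_homa_adjusted"] for s in (MHO, MUO)},
        n={MHO: params.n_mho, MUO: params.n_muo},
    )
    return table, truth


# ---------------------------------------------------------------------------
# validation experiments

def _support_mask(rp: np.ndarray) -> np.ndarray:
    """Boolean upper-triangle support of designated true edges.

    Requires a clean support: every off-diagonal entry either 0 or of
    magnitude >= 0.3.
    """
    iu = np.triu_indices(len(rp), k=1)
    off = rp[iu]
    bad = (off != 0.0) & (np.abs(off) < 0.3)
    if bad.any():
        raise ConfigurationError(
            "recovery experiments need a designated support: nonzero target "
            "partial correlations must have |Rp| >= 0.3"
        )
    return off != 0.0


@dataclass
class RecoveryReport:
    """Edge-recovery rates of the full generate->stratify->estimate->select
    pipeline, with Monte-Carlo standard errors."""

    n_replicates: int
    selection_mode: str
    threshold: float
    strata: dict                  # stratum -> summary dict
    per_pair: pd.DataFrame        # one row per (stratum, pair)

    def to_json_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "selection_mode": self.selection_mode,
            "threshold": self.threshold,
            "strata": self.strata,
        }


def recovery_experiment(
    params: SyntheticCohortParams,
    n_replicates: int = 20,
    selection_mode: str = "pvalue",
    threshold: float = 0.25,
) -> RecoveryReport:
    """Monte-Carlo edge recovery: sensitivity on true edges, false-positive
    rate on null pairs, per stratum."""
    schema = params.schema
    iu = np.triu_indices(schema.n_nodes, k=1)
    supports = {s: _support_mask(params.target_rp(s)) for s in (MHO, MUO)}
    counts = {s: np.zeros(len(iu[0])) for s in (MHO, MUO)}
    rep_seeds = np.random.SeedSequence(params.seed).generate_state(n_replicates + 2)[2:]
    for rep in range(n_replicates):
        rep_params = dataclasses.replace(params, seed=int(rep_seeds[rep]) & 0x7FFFFFFF)
        cohort, _ = generate_cohort(rep_params)
        strat = stratify_cohort(cohort)
        for stratum in (MHO, MUO):
            est = PartialCorrelationNetwork(selection_mode=selection_mode,
                                            threshold=threshold)
            est.fit(strat.stratum(stratum))
            selected = est.edges_["selected"].to_numpy()
            counts[stratum] += selected.astype(float)

    strata_summary, rows = {}, []
    for stratum in (MHO, MUO):
        freq = counts[stratum] / n_replicates
        sup = supports[stratum]
        sens = float(freq[sup].mean()) if sup.any() else float("nan")
        fpr = float(freq[~sup].mean()) if (~sup).any() else float("nan")
        n_true_trials = int(sup.sum()) * n_replicates
        n_null_trials = int((~sup).sum()) * n_replicates
        strata_summary[stratum] = {
            "n": params.n(stratum),
            "n_true_edges": int(sup.sum()),
            "n_null_pairs": int((~sup).sum()),
            "sensitivity": sens,
            "sensitivity_mc_se": float(np.sqrt(max(sens * (1 - sens), 0.0) / n_true_trials))
            if sup.any() else float("nan"),
            "false_positive_rate": fpr,
            "false_positive_rate_mc_se": float(np.sqrt(max(fpr * (1 - fpr), 0.0) / n_null_trials))
            if (~sup).any() else float("nan"),
        }
        for k in range(len(iu[0])):
            rows.append({
                "stratum": stratum,
                "node_i": schema.nodes[iu[0][k]],
                "node_j": schema.nodes[iu[1][k]],
                "true_edge": bool(sup[k]),
                "selection_rate": float(freq[k]),
            })
    return RecoveryReport(
        n_replicates=n_replicates,
        selection_mode=selection_mode,
        threshold=threshold,
        strata=strata_summary,
        per_pair=pd.DataFrame(rows),
    )


def selection_calibration_experiment(
    n: int = 150,
    n_replicates: int = 500,
    threshold: float = 0.25,
    seed: int = 0,
    selection_mode: str = "pvalue",
) -> dict:
    """Null calibration of the selection rule.

    Generates single strata with a zero true partial-correlation matrix
    (healthy-stratum margins) and records how often each of the 78 pairs
    is selected.  Under the null, the p-value rule is a level-``threshold``
    test per pair, so the empirical frequency should sit at the threshold
    up to Monte-Carlo error.
    """
    params = SyntheticCohortParams(
        n_mho=n, n_muo=15, scenario={MHO: "null", MUO: "null"}, seed=seed,
    )
    schema = params.schema
    iu = np.triu_indices(schema.n_nodes, k=1)
    counts = np.zeros(len(iu[0]))
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates + 1)[1:]
    for rep in range(n_replicates):
        df, _ = _generate_stratum(params, MHO, int(rep_seeds[rep]) & 0x7FFFFFFF)
        est = PartialCorrelationNetwork(selection_mode=selection_mode, threshold=threshold)
        est.fit(df[list(schema.nodes)])
        counts += est.edges_["selected"].to_numpy().astype(float)
    freq = counts / n_replicates
    return {
        "n": n,
        "n_replicates": n_replicates,
        "threshold": threshold,
        "mean_selection_rate": float(freq.mean()),
        "min_pair_rate": float(freq.min()),
        "max_pair_rate": float(freq.max()),
        "mc_se_per_pair": float(np.sqrt(threshold * (1 - threshold) / n_replicates)),
        "per_pair_rate": freq.tolist(),
    }
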
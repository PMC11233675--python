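"""Repeated-measures ASCA for longitudinal multivariate data.

Each variable of a scaled observations x variables matrix is modelled with a
linear mixed model containing a categorical time effect, a time x group
interaction and a random intercept per fermentation vessel.  The baseline
time point anchors the model: interaction columns for the baseline (and for
the reference group) are removed, encoding the assumption that groups are
indistinguishable before fermentation starts.  The fitted fixed effects are
assembled into effect matrices (one per model term), each summarised by a
simultaneous component analysis (PCA via SVD); nonparametric bootstrap over
vessels yields 95% confidence envelopes for the group score trajectories and
the loadings.

A note on estimators.  GLS at the REML variances coincides with ordinary
least squares exactly when the fixed-effect column space is invariant under
vessel averaging (Zyskind's condition) — true for time-only models on
complete balanced data, but not for the baseline-constrained multi-group
model, where pooling the baseline across groups lets the random intercept
reweight information.  The default pipeline therefore estimates fixed
effects by OLS throughout (point fit and resampling refits use the same
projection estimator, so the envelopes are calibrated for the statistics
they cover), while ``engine="mixedlm"`` provides the REML/GLS coefficients
and variance components of the per-variable mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ScaledMatrix
from .utils import greedy_match, rng_stream

__all__ = [
    "LongitudinalModelSpec",
    "DesignMatrices",
    "EffectDecomposition",
    "ScaResult",
    "ValidationEnvelope",
    "build_design",
    "fit_lmm",
    "effect_matrices",
    "sca_decompose",
    "rank_loadings",
    "RMASCA",
    "RMASCAResults",
]


@dataclass(frozen=True)
class LongitudinalModelSpec:
    """Model structure: baseline anchoring and term layout.

    Fixed effects are ``time`` (categorical, dummies against the baseline
    time point) and ``time:group`` (dummies for non-baseline times and
    non-reference groups only); there is no group main effect — groups are
    assumed equal at baseline, which the removal of baseline interaction
    columns enforces.  The random term is an intercept per vessel.
    """

    baseline_time: float
    reference_group: str
    random_effect: str = "vessel"
    scaling: str = ""


@dataclass
class DesignMatrices:
    """Fixed design X (named columns), vessel indicators Z, aligned metadata."""

    X: pd.DataFrame
    Z: pd.DataFrame
    meta: pd.DataFrame
    time_columns: list
    interaction_columns: list

    @property
    def vessel_labels(self) -> pd.Series:
        return self.meta["vessel"]


def build_design(meta: pd.DataFrame, spec: LongitudinalModelSpec) -> DesignMatrices:
    """Construct the fixed and random design matrices.

    ``meta`` needs group, replicate and time_h per observation (a ``vessel``
    column overrides the default group x replicate vessel identity).  Time is
    coded as categorical dummies against the baseline; interaction dummies
    exist only for non-baseline times and non-reference groups, so the
    column count for G groups and T times is ``1 + (T−1) + (T−1)(G−1)``.
    """
    required = {"group", "replicate", "time_h"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    meta = meta.reset_index(drop=True).copy()
    if "vessel" in meta.columns:
        by_vessel = meta.groupby("vessel", observed=True)["group"].nunique()
        bad = by_vessel[by_vessel > 1].index.tolist()
        if bad:
            raise ValueError(f"vessel(s) observed in more than one group: {bad}")
    else:
        meta["vessel"] = meta["group"].astype(str) + "-R" + meta["replicate"].astype(str)
    times = sorted(meta["time_h"].unique())
    groups = sorted(meta["group"].unique())
    if spec.baseline_time not in times:
        raise ValueError(f"baseline time {spec.baseline_time} not present in data")
    if spec.reference_group not in groups:
        raise ValueError(f"reference group {spec.reference_group!r} not present in data")
    for vessel, sub in meta.groupby("vessel", observed=True):
        if spec.baseline_time not in set(sub["time_h"]):
            raise ValueError(f"vessel {vessel!r} lacks the baseline time point")
    nb_times = [t for t in times if t != spec.baseline_time]
    nr_groups = [g for g in groups if g != spec.reference_group]
    cols = {"Intercept": np.ones(len(meta))}
    time_cols, inter_cols = [], []
    for t in nb_times:
        name = f"time[{t:g}]"
        cols[name] = (meta["time_h"] == t).to_numpy(dtype=float)
        time_cols.append(name)
    for t in nb_times:
        for g in nr_groups:
            name = f"time[{t:g}]:group[{g}]"
            cols[name] = (
                (meta["time_h"] == t) & (meta["group"] == g)
            ).to_numpy(dtype=float)
            inter_cols.append(name)
    X = pd.DataFrame(cols)
    Z = pd.get_dummies(meta["vessel"]).astype(float)
    return DesignMatrices(X=X, Z=Z, meta=meta, time_columns=time_cols,
                          interaction_columns=inter_cols)


@dataclass
class LmmFit:
    """Per-variable mixed-model estimates."""

    params: pd.Series
    re_var: float
    resid_var: float
    converged: bool
    flags: list = field(default_factory=list)


def fit_lmm(y: np.ndarray, design: DesignMatrices, reml: bool = True) -> LmmFit:
    """Fit one variable's random-intercept model.

    REML variance components with GLS fixed effects, via statsmodels MixedLM.
    On designs satisfying Zyskind's condition (the fixed-effect column space
    closed under vessel averaging, e.g. complete balanced time-only models)
    the GLS fixed effects equal ordinary least squares exactly.  Exact
    interpolation (numerically zero OLS residual) short-circuits to the OLS
    solution with both variance components zero — the REML surface is
    degenerate there.  Non-convergence falls back to OLS fixed effects and is
    flagged, never silent.
    """
    y = np.asarray(y, dtype=float)
    X = design.X.to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("response length does not match design rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_ols) ** 2))
    names = list(design.X.columns)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        return LmmFit(params=pd.Series(beta_ols, index=names), re_var=0.0,
                      resid_var=0.0, converged=True, flags=["exact-fit"])
    import statsmodels.api as sm

    flags = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=design.vessel_labels.to_numpy())
            result = model.fit(reml=reml)
        re_var = float(np.asarray(result.cov_re)[0, 0])
        resid_var = float(result.scale)
        params = pd.Series(np.asarray(result.fe_params), index=names)
        converged = bool(getattr(result, "converged", True))
        if not converged:
            flags.append("non-convergence")
        if re_var < 0:
            re_var = 0.0
            flags.append("negative-re-variance-truncated")
    except Exception as exc:  # noqa: BLE001 - report, not silent
        params = pd.Series(beta_ols, index=names)
        re_var = 0.0
        resid_var = rss / max(1, y.size - X.shape[1])
        converged = False
        flags.append(f"mixedlm-failed: {type(exc).__name__}")
    return LmmFit(params=params, re_var=re_var, resid_var=resid_var,
                  converged=converged, flags=flags)


@dataclass
class EffectDecomposition:
    """Fixed-effect coefficient matrix and per-term effect matrices."""

    coefficients: pd.DataFrame      # p x V
    M_time: pd.DataFrame            # N x V
    M_interaction: pd.DataFrame     # N x V
    M_combined: pd.DataFrame        # N x V
    residuals: pd.DataFrame         # N x V
    variance_components: pd.DataFrame  # V x (re_var, resid_var, converged)


def effect_matrices(coefficients: pd.DataFrame, design: DesignMatrices,
                    Y: pd.DataFrame | None = None,
                    variance_components: pd.DataFrame | None = None
                    ) -> EffectDecomposition:
    """Build the per-term effect matrices ``M = X_term · B̂_term``.

    Only the term's own design columns contribute, so rows for baseline
    observations have zero interaction contribution and ``M_combined`` is
    exactly ``M_time + M_interaction``.
    """
    missing = [c for c in design.X.columns if c not in coefficients.index]
    if missing:
        raise ValueError(f"coefficients missing for design columns: {missing}")
    variables = list(coefficients.columns)
    B = coefficients.loc[list(design.X.columns)]
    Xt = design.X[design.time_columns].to_numpy(dtype=float)
    Bt = B.loc[design.time_columns].to_numpy(dtype=float)
    M_time = Xt @ Bt if design.time_columns else np.zeros((len(design.X), len(variables)))
    if design.interaction_columns:
        Xi = design.X[design.interaction_columns].to_numpy(dtype=float)
        Bi = B.loc[design.interaction_columns].to_numpy(dtype=float)
        M_inter = Xi @ Bi
    else:
        M_inter = np.zeros((len(design.X), len(variables)))
    idx = design.meta.index
    M_time = pd.DataFrame(M_time, columns=variables, index=idx)
    M_inter = pd.DataFrame(M_inter, columns=variables, index=idx)
    M_comb = M_time + M_inter
    if Y is not None:
        fitted = design.X.to_numpy(dtype=float) @ B.to_numpy(dtype=float)
        residuals = pd.DataFrame(
            Y.to_numpy(dtype=float) - fitted, columns=variables, index=idx
        )
    else:
        residuals = pd.DataFrame(np.zeros_like(M_comb.to_numpy()),
                                 columns=variables, index=idx)
    if variance_components is None:
        variance_components = pd.DataFrame(
            {"re_var": np.nan, "resid_var": np.nan, "converged": True},
            index=variables,
        )
    return EffectDecomposition(
        coefficients=B, M_time=M_time, M_interaction=M_inter,
        M_combined=M_comb, residuals=residuals,
        variance_components=variance_components,
    )


@dataclass
class ScaResult:
    """Simultaneous component analysis of one effect matrix."""

    scores: pd.DataFrame           # N x R, columns PC1..PCR
    loadings: pd.DataFrame         # V x R, orthonormal columns
    explained_pct: np.ndarray      # length R, non-increasing
    trajectories: pd.DataFrame | None = None  # group, time_h, component, score

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def sca_decompose(effect_matrix: pd.DataFrame, n_components: int | None = None,
                  row_meta: pd.DataFrame | None = None) -> ScaResult:
    """PCA of an effect matrix via SVD.

    Explained variance per component is the squared singular value over the
    matrix's total sum of squares.  Each component is oriented so its
    largest-magnitude loading is positive — a deterministic sign convention.
    Requesting more components than the rank truncates with a warning; a
    zero effect matrix is an error ("no effect").
    """
    M = np.asarray(effect_matrix, dtype=float)
    variables = list(effect_matrix.columns) if hasattr(effect_matrix, "columns") else [
        f"var_{i}" for i in range(M.shape[1])
    ]
    total = float(np.sum(M * M))
    if total <= 0.0:
        raise ValueError("effect matrix is zero: no effect to decompose")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(M.shape) * np.finfo(float).eps))
    R = rank if n_components is None else int(n_components)
    if R > rank:
        warnings.warn(
            f"requested {R} components but effect matrix rank is {rank}; truncating",
            stacklevel=2,
        )
        R = rank
    U, s, Vt = U[:, :R], s[:R], Vt[:R]
    loadings = Vt.T
    scores = U * s
    for r in range(R):
        j = int(np.argmax(np.abs(loadings[:, r])))
        if loadings[j, r] < 0:
            loadings[:, r] *= -1.0
            scores[:, r] *= -1.0
    comp_names = [f"PC{r + 1}" for r in range(R)]
    explained = 100.0 * s**2 / total
    scores_df = pd.DataFrame(scores, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=variables, columns=comp_names)
    trajectories = None
    if row_meta is not None:
        tmp = scores_df.copy()
        tmp["group"] = row_meta["group"].to_numpy()
        tmp["time_h"] = row_meta["time_h"].to_numpy()
        trajectories = (
            tmp.groupby(["group", "time_h"], observed=True)[comp_names]
            .mean()
            .reset_index()
            .melt(id_vars=["group", "time_h"], var_name="component",
                  value_name="score")
        )
    return ScaResult(scores=scores_df, loadings=loadings_df,
                     explained_pct=explained, trajectories=trajectories)


def rank_loadings(sca: ScaResult, component: int = 1, k: int = 12) -> pd.DataFrame:
    """Top-k and bottom-k variables by signed loading on one component.

    By the usual reading of these models, variables with negative loadings
    increase in abundance over time while positive loadings indicate
    consumption — a caption convention that depends on the score
    orientation, not a property enforced here.  Output order is
    deterministic (loading value, then variable name).
    """
    col = f"PC{component}"
    if col not in sca.loadings.columns:
        raise ValueError(f"component {component} not available")
    V = sca.loadings.shape[0]
    if k > V:
        raise ValueError(f"k={k} exceeds the number of variables ({V})")
    s = sca.loadings[col]
    frame = pd.DataFrame({"variable": s.index, "loading": s.to_numpy()})
    top = frame.sort_values(["loading", "variable"],
                            ascending=[False, True]).head(k)
    bottom = frame.sort_values(["loading", "variable"],
                               ascending=[True, True]).head(k)
    top = top.assign(direction="top")
    bottom = bottom.assign(direction="bottom")
    return pd.concat([top, bottom], ignore_index=True)


@dataclass
class ValidationEnvelope:
    """Percentile confidence envelopes from resampling vessels."""

    n_resamples: int
    level: float
    method: str
    score_ci: pd.DataFrame    # group, time_h, component, lower, point, upper
    loading_ci: pd.DataFrame  # variable, component, lower, point, upper
    n_unmatched_components: int = 0
    n_redrawn: int = 0

    def separated_timepoints(self, component: int = 1,
                             groups: Sequence[str] | None = None) -> list[float]:
        """Times at which at least one group pair has disjoint score CIs."""
        col = f"PC{component}"
        sub = self.score_ci[self.score_ci["component"] == col]
        if groups is not None:
            sub = sub[sub["group"].isin(groups)]
        scale = float(np.abs(sub[["lower", "upper"]].to_numpy()).max() or 1.0)
        tol = 1e-9 * scale  # guards against spurious splits at float noise
        out = []
        for t, block in sub.groupby("time_h"):
            rows = block.reset_index(drop=True)
            sep = False
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    lo_i, hi_i = rows.loc[i, ["lower", "upper"]]
                    lo_j, hi_j = rows.loc[j, ["lower", "upper"]]
                    if hi_i < lo_j - tol or hi_j < lo_i - tol:
                        sep = True
            if sep:
                out.append(float(t))
        return sorted(out)


class RMASCA:
    """Repeated-measures ASCA model for a scaled longitudinal matrix.

    Parameters
    ----------
    scaled
        Output of :func:`volatempo.preprocess.scale_matrix`.
    baseline_time
        Anchor time point; defaults to the earliest observed time.
    reference_group
        Group absorbed into the time effect (no interaction columns);
        defaults to the alphabetically first group.
    n_components
        Number of SCA components to retain per effect matrix.
    """

    def __init__(self, scaled: ScaledMatrix, baseline_time: float | None = None,
                 reference_group: str | None = None, n_components: int = 3):
        meta = scaled.row_meta
        if baseline_time is None:
            baseline_time = float(meta["time_h"].min())
        if reference_group is None:
            reference_group = sorted(meta["group"].unique())[0]
        self.scaled = scaled
        self.spec = LongitudinalModelSpec(
            baseline_time=float(baseline_time),
            reference_group=str(reference_group),
            scaling=scaled.method,
        )
        self.design = build_design(meta, self.spec)
        self.n_components = int(n_components)

    @classmethod
    def from_peak_table(cls, table: pd.DataFrame, scaling: str = "unit-sd",
                        **kwargs) -> "RMASCA":
        from .preprocess import scale_matrix

        return cls(scale_matrix(table, method=scaling), **kwargs)

    # ----------------------------------------------------------------- fit

    def fit(self, engine: str = "ols") -> "RMASCAResults":
        """Estimate the per-variable models and decompose the effect matrices.

        ``engine="ols"`` (default) estimates fixed effects by least squares —
        the projection estimator whose resampling distribution the bootstrap
        reproduces exactly.  ``engine="mixedlm"`` fits REML random-intercept
        models per variable, yielding GLS fixed effects plus vessel and
        residual variance components; the two coincide whenever the design
        satisfies Zyskind's condition (e.g. time-only models on complete
        balanced data).
        """
        if engine not in ("mixedlm", "ols"):
            raise ValueError(f"unknown engine {engine!r}")
        Y = self.scaled.values
        variables = list(Y.columns)
        X = self.design.X.to_numpy(dtype=float)
        if engine == "ols":
            B, *_ = np.linalg.lstsq(X, Y.to_numpy(dtype=float), rcond=None)
            coef = pd.DataFrame(B, index=self.design.X.columns, columns=variables)
            vc = pd.DataFrame({"re_var": np.nan, "resid_var": np.nan,
                               "converged": True}, index=variables)
        else:
            cols, vc_rows = {}, []
            for v in variables:
                f = fit_lmm(Y[v].to_numpy(dtype=float), self.design)
                cols[v] = f.params
                vc_rows.append(
                    {"re_var": f.re_var, "resid_var": f.resid_var,
                     "converged": f.converged, "flags": ";".join(f.flags)}
                )
            coef = pd.DataFrame(cols)
            vc = pd.DataFrame(vc_rows, index=variables)
        decomposition = effect_matrices(coef, self.design, Y=Y,
                                        variance_components=vc)
        sca = {}
        for effect, M in (
            ("time", decomposition.M_time),
            ("interaction", decomposition.M_interaction),
            ("combined", decomposition.M_combined),
        ):
            try:
                sca[effect] = sca_decompose(M, self.n_components,
                                            row_meta=self.design.meta)
            except ValueError:
                sca[effect] = None  # zero effect matrix (e.g. single group)
        return RMASCAResults(model=self, decomposition=decomposition, sca=sca,
                             engine=engine)


@dataclass
class RMASCAResults:
    """Fitted RM-ASCA model: effect decomposition and SCA per effect."""

    model: RMASCA
    decomposition: EffectDecomposition
    sca: dict
    engine: str

    def sca_for(self, effect: str = "combined") -> ScaResult:
        if effect not in self.sca:
            raise ValueError(f"unknown effect {effect!r}")
        if self.sca[effect] is None:
            raise ValueError(f"effect {effect!r} matrix was zero: no effect")
        return self.sca[effect]

    def rank_loadings(self, component: int = 1, k: int = 12,
                      effect: str = "combined") -> pd.DataFrame:
        return rank_loadings(self.sca_for(effect), component=component, k=k)

    # ------------------------------------------------------------ bootstrap

    def bootstrap(self, n_resamples: int = 1000, level: float = 0.95,
                  seed: int = 0, effect: str = "combined",
                  method: str = "bootstrap", interval: str = "auto",
                  congruence_threshold: float = 0.5) -> ValidationEnvelope:
        """Resampling validation of scores and loadings.

        ``method="bootstrap"`` draws vessels with replacement within each
        group and refits the whole pipeline (fixed effects -> effect matrix
        -> SCA) per resample; ``method="jackknife"`` instead leaves one
        vessel out at a time (``n_resamples`` is then the vessel count).
        Bootstrap draws use the m = n−1 convention per group: resampling
        n−1 of n vessels makes the resampled group mean's variance an
        unbiased estimate of the true sampling variance (the plain n-of-n
        bootstrap understates it by the factor (n−1)/n, a serious bias at
        the 3 vessels typical of fermentation studies).
        Each resample's components are aligned to the point estimate by
        greedy congruence matching with sign flipping; components whose best
        match falls below ``congruence_threshold`` are dropped from the
        envelopes and counted.  Effect matrices are always evaluated on the
        original design rows so trajectories are comparable across resamples.

        Interval construction differs by statistic under ``interval="auto"``
        (default).  Loadings are norm-constrained direction cosines whose
        resampled values are attenuation-biased (a noisier fit rotates the
        component further toward noise directions), so their envelopes use
        the basic (reverse-percentile) interval ``[2θ̂ − q_hi, 2θ̂ − q_lo]``,
        which undoes that first-order bias.  Group-mean score trajectories
        are approximately unbiased linear functionals, so their envelopes
        use the plain percentile band — re-centring would only double the
        point estimate's own noise.  ``interval="basic"`` or
        ``"percentile"`` forces one construction for both.  All intervals
        collapse to zero width when replicate vessels are identical.
        """
        if method not in ("bootstrap", "jackknife"):
            raise ValueError(f"unknown method {method!r}")
        if interval not in ("auto", "basic", "percentile"):
            raise ValueError(f"unknown interval type {interval!r}")
        point = self.sca_for(effect)
        design = self.model.design
        meta = design.meta
        X = design.X.to_numpy(dtype=float)
        Y = self.model.scaled.values.to_numpy(dtype=float)
        variables = list(self.model.scaled.values.columns)
        col_names = list(design.X.columns)
        if effect == "time":
            eff_cols = design.time_columns
        elif effect == "interaction":
            eff_cols = design.interaction_columns
        else:
            eff_cols = design.time_columns + design.interaction_columns
        eff_idx = [col_names.index(c) for c in eff_cols]
        X_eff = X[:, eff_idx]
        # per-vessel sufficient statistics: resampled normal equations are
        # count-weighted sums, so a refit costs one small solve
        vessels_by_group: dict = {}
        G_v, H_v = {}, {}
        for vessel, sub in meta.groupby("vessel", observed=True):
            g = sub["group"].iloc[0]
            vessels_by_group.setdefault(g, []).append(vessel)
            rows = sub.index.to_numpy()
            Xv = X[rows]
            G_v[vessel] = Xv.T @ Xv
            H_v[vessel] = Xv.T @ Y[rows]
        for g in vessels_by_group:
            if len(vessels_by_group[g]) < 2:
                raise ValueError(
                    f"group {g!r} has fewer than 2 vessels; resampling impossible"
                )
            vessels_by_group[g] = sorted(vessels_by_group[g])
        rng = rng_stream(seed, "rmasca-bootstrap")
        if method == "jackknife":
            all_vessels = sorted(v for vs in vessels_by_group.values() for v in vs)
            draws = []
            for left_out in all_vessels:
                draws.append([v for v in all_vessels if v != left_out])
            n_resamples = len(draws)
        else:
            draws = []
            for _ in range(n_resamples):
                chosen = []
                for g in sorted(vessels_by_group):
                    vs = vessels_by_group[g]
                    m = len(vs) - 1 if len(vs) >= 3 else len(vs)
                    chosen.extend(rng.choice(vs, size=m, replace=True))
                draws.append(chosen)
        R = point.n_components
        P0 = point.loadings.to_numpy(dtype=float)
        traj_key = meta[["group", "time_h"]]
        comp_names = list(point.loadings.columns)
        boot_loadings = [[] for _ in range(R)]
        boot_traj = [[] for _ in range(R)]
        n_unmatched = 0
        ridge = 1e-10 * np.eye(X.shape[1])
        for chosen in draws:
            G = sum(G_v[v] for v in chosen)
            H = sum(H_v[v] for v in chosen)
            B = np.linalg.solve(G + ridge, H)
            M = X_eff @ B[eff_idx]
            if not np.any(M):
                # degenerate resample with a zero effect matrix: envelopes
                # collapse to zero for every matched component
                loadings_b = np.zeros_like(P0)
                scores_b = np.zeros((M.shape[0], R))
            else:
                U, s, Vt = np.linalg.svd(M, full_matrices=False)
                r_b = min(R, s.size)
                loadings_b = Vt[:r_b].T
                scores_b = U[:, :r_b] * s[:r_b]
            pairs, signs, values = greedy_match(P0, loadings_b)
            matched = {}
            for (i, j), sgn, val in zip(pairs, signs, values):
                if val >= congruence_threshold:
                    matched[i] = (j, sgn)
                else:
                    n_unmatched += 1
            for r in range(R):
                if r not in matched:
                    continue
                j, sgn = matched[r]
                boot_loadings[r].append(sgn * loadings_b[:, j])
                tr = (
                    pd.DataFrame({"group": traj_key["group"],
                                  "time_h": traj_key["time_h"],
                                  "score": sgn * scores_b[:, j]})
                    .groupby(["group", "time_h"], observed=True)["score"]
                    .mean()
                )
                boot_traj[r].append(tr)
        lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2

        score_interval = "percentile" if interval == "auto" else interval
        loading_interval = "basic" if interval == "auto" else interval

        def _ci(samples: np.ndarray, pt: float, kind: str) -> tuple[float, float]:
            lo = float(np.percentile(samples, lo_q))
            hi = float(np.percentile(samples, hi_q))
            if kind == "basic":
                lo, hi = 2 * pt - hi, 2 * pt - lo
            return min(lo, pt), max(hi, pt)

        point_traj = point.trajectories.set_index(["group", "time_h", "component"])
        score_rows, loading_rows = [], []
        for r in range(R):
            comp = comp_names[r]
            if boot_traj[r]:
                traj_mat = pd.concat(boot_traj[r], axis=1).to_numpy()
                for i, (g, t) in enumerate(
                    pd.concat(boot_traj[r], axis=1).index
                ):
                    pt = float(point_traj.loc[(g, t, comp), "score"])
                    l, h = _ci(traj_mat[i], pt, score_interval)
                    score_rows.append(
                        {"group": g, "time_h": t, "component": comp,
                         "lower": l, "point": pt, "upper": h}
                    )
                L = np.column_stack(boot_loadings[r])
                for i, v in enumerate(variables):
                    pt = float(point.loadings.loc[v, comp])
                    l, h = _ci(L[i], pt, loading_interval)
                    loading_rows.append(
                        {"variable": v, "component": comp, "lower": l,
                         "point": pt, "upper": h}
                    )
        return ValidationEnvelope(
            n_resamples=n_resamples, level=level, method=method,
            score_ci=pd.DataFrame(score_rows),
            loading_ci=pd.DataFrame(loading_rows),
            n_unmatched_components=n_unmatched, n_redrawn=0,
        )

    # -------------------------------------------------------------- summary

    def summary(self) -> str:
        lines = ["RM-ASCA Results", "==============="]
        lines.append(f"engine:            {self.engine}")
        lines.append(f"baseline time:     {self.model.spec.baseline_time:g} h")
        lines.append(f"reference group:   {self.model.spec.reference_group}")
        lines.append(f"observations:      {len(self.model.design.X)}")
        lines.append(f"variables:         {self.decomposition.M_combined.shape[1]}")
        for effect in ("time", "interaction", "combined"):
            sca = self.sca.get(effect)
            if sca is None:
                lines.append(f"{effect:<12s} effect: zero matrix")
                continue
            ev = ", ".join(
                f"PC{r + 1} {v:.2f}%" for r, v in enumerate(sca.explained_pct)
            )
            lines.append(f"{effect:<12s} effect: {ev}")
        vc = self.decomposition.variance_components
        if vc["re_var"].notna().any():
            lines.append(
                "variance components (median across variables): "
                f"vessel {vc['re_var'].median():.4f}, "
                f"residual {vc['resid_var'].median():.4f}"
            )
        return "\n".join(lines)
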
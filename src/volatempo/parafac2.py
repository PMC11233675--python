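"""PARAFAC2 decomposition of interval-segmented GC-MS data.

PARAFAC2 models each sample slab as ``X_k ≈ B_k diag(c_k) Aᵀ`` where the
spectra ``A`` (m/z x F) and concentrations ``c_k`` are shared-mode factors
and the elution profiles ``B_k`` are sample-specific, constrained only by a
constant cross-product ``B_kᵀB_k``.  This resolves co-eluting compounds whose
retention times shift between samples — the defining nuisance of headspace
GC-MS time series.

The fitting algorithm is the classic direct-fit alternating scheme: the
cross-product constraint is imposed by writing ``B_k = P_k B`` with ``P_k``
orthonormal, updating each ``P_k`` by a Procrustes step and the remaining
factors by one CP-ALS pass on the projected array ``Y_k = P_kᵀ X_k``.
Non-negativity on spectra and concentrations uses exact HALS column updates,
so the penalized residual is non-increasing at every iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tensor import ThreeWayTensor
from .utils import rng_stream

__all__ = [
    "Parafac2Factors",
    "Parafac2",
    "Parafac2Results",
    "ModelSelectionReport",
    "fit_parafac2",
    "core_consistency",
    "select_components",
]

_EPS = np.finfo(float).eps


@dataclass
class Parafac2Factors:
    """Ground-truth or estimated PARAFAC2 factors.

    ``spectra`` is J x F with unit-norm columns, ``elution_profiles`` holds
    K matrices of shape I_k x F, ``concentrations`` is K x F with the model
    scale absorbed.
    """

    spectra: np.ndarray
    elution_profiles: list[np.ndarray]
    concentrations: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.spectra.shape[1])

    def reconstruct(self) -> list[np.ndarray]:
        """Noise-free slabs ``B_k diag(c_k) Aᵀ``."""
        return [
            Bk @ np.diag(ck) @ self.spectra.T
            for Bk, ck in zip(self.elution_profiles, self.concentrations)
        ]

    def cross_product_deviation(self) -> float:
        """max_k ‖B_kᵀB_k − B_0ᵀB_0‖_F — zero for a valid PARAFAC2 structure."""
        ref = self.elution_profiles[0].T @ self.elution_profiles[0]
        return float(
            max(np.linalg.norm(Bk.T @ Bk - ref) for Bk in self.elution_profiles)
        )


def _hals_update(F_mat: np.ndarray, gram: np.ndarray, target: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """One exact non-negative HALS sweep: argmin over each column with the
    others fixed, projected to the non-negative orthant."""
    for f in range(F_mat.shape[1]):
        denom = gram[f, f]
        if denom <= _EPS:
            continue
        col = F_mat[:, f] + (target[:, f] - F_mat @ gram[:, f]) / denom
        np.maximum(col, 0.0, out=col)
        if not col.any():  # dead component: tiny reseed keeps ALS moving
            col = 1e-12 * rng.uniform(0.5, 1.0, size=col.shape)
        F_mat[:, f] = col
    return F_mat


class Parafac2:
    """PARAFAC2 model for a :class:`~volatempo.tensor.ThreeWayTensor`.

    Parameters
    ----------
    tensor
        Interval data, K slabs of I_k scans x J m/z bins.
    n_components
        Number of co-eluting compounds F to resolve; must not exceed
        min(I_k, J, K).
    nonneg_spectra, nonneg_concentrations
        Non-negativity on the physically non-negative modes (default on).
    elution
        ``"free"`` (classic direct fit, default) or ``"nonnegative"``
        (flexible coupling: B_k non-negative with a quadratic penalty pulling
        them toward a common cross-product).
    """

    def __init__(self, tensor: ThreeWayTensor, n_components: int, *,
                 nonneg_spectra: bool = True, nonneg_concentrations: bool = True,
                 elution: str = "free"):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        bound = tensor.min_dimension()
        if n_components > bound:
            raise ValueError(
                f"n_components={n_components} exceeds min(I_k, J, K)={bound}"
            )
        if elution not in ("free", "nonnegative"):
            raise ValueError(f"unknown elution mode {elution!r}")
        self.tensor = tensor
        self.n_components = int(n_components)
        self.nonneg_spectra = nonneg_spectra
        self.nonneg_concentrations = nonneg_concentrations
        self.elution = elution

    # ------------------------------------------------------------------ fit

    def fit(self, *, seed: int = 0, tol: float = 1e-8, max_iter: int = 2000,
            n_restarts: int = 10, screen_iter: int = 150) -> "Parafac2Results":
        """Fit by multi-start ALS.

        All restarts (one SVD-initialised, the rest random) are screened for
        ``screen_iter`` iterations; the best is refined to convergence
        (relative objective change below ``tol`` or ``max_iter`` iterations).
        """
        if self.elution == "nonnegative":
            return self._fit_flexible(seed=seed, tol=tol, max_iter=max_iter)
        X = self.tensor.slabs
        total_ss = self.tensor.total_ss()
        if total_ss == 0.0:
            raise ValueError("tensor is identically zero")
        rng = rng_stream(seed, "parafac2")
        restart_losses = []
        best = None
        for r in range(max(1, n_restarts)):
            init = self._init_factors(rng, svd_init=(r == 0))
            state = self._als(X, *init, tol=tol,
                              max_iter=min(screen_iter, max_iter), rng=rng)
            restart_losses.append(state["loss"])
            if best is None or state["loss"] < best["loss"]:
                best = state
        # refine the winning start to full convergence
        state = self._als(X, best["A"], best["B"], best["C"], tol=tol,
                          max_iter=max_iter, rng=rng,
                          loss_history=best["history"])
        return self._finalize(state, total_ss, restart_losses)

    def _init_factors(self, rng, svd_init: bool):
        J, F, K = self.tensor.n_mz, self.n_components, self.tensor.n_samples
        if svd_init:
            S = sum(Xk.T @ Xk for Xk in self.tensor.slabs)
            _, vecs = np.linalg.eigh(S)
            A = np.abs(vecs[:, ::-1][:, :F])
            C = np.tile(
                np.array([np.linalg.norm(Xk) for Xk in self.tensor.slabs])[:, None],
                (1, F),
            ) / max(1, F)
            B = np.eye(F)
        else:
            A = rng.uniform(0.1, 1.0, size=(J, F))
            B = np.eye(F) + 0.1 * rng.standard_normal((F, F))
            C = rng.uniform(0.5, 1.5, size=(K, F))
        return A, B, C

    def _als(self, X, A, B, C, *, tol, max_iter, rng, loss_history=None):
        K, F = len(X), self.n_components
        J = self.tensor.n_mz
        total_ss = self.tensor.total_ss()
        history = list(loss_history) if loss_history else []
        loss_prev = history[-1] if history else np.inf
        converged = False
        A, B, C = A.copy(), B.copy(), C.copy()
        P = [None] * K
        Y = np.empty((K, F, J))
        proj_loss = np.empty(K)
        for it in range(max_iter):
            # Procrustes step: optimal orthonormal P_k given the CP factors
            for k, Xk in enumerate(X):
                M = Xk @ (A * C[k]) @ B.T  # I_k x F
                U, _, Vt = np.linalg.svd(M, full_matrices=False)
                P[k] = U @ Vt
                Y[k] = P[k].T @ Xk
                proj_loss[k] = np.sum(Xk * Xk) - np.sum(Y[k] * Y[k])
            # one CP-ALS pass on the projected trilinear array Y
            G = (C.T @ C) * (A.T @ A)
            H = np.einsum("kfj,jg,kg->fg", Y, A, C)
            B = np.linalg.solve(G + _EPS * np.eye(F), H.T).T
            GA = (C.T @ C) * (B.T @ B)
            HA = np.einsum("kfj,fg,kg->jg", Y, B, C)
            if self.nonneg_spectra:
                A = _hals_update(A, GA, HA, rng)
            else:
                A = np.linalg.solve(GA + _EPS * np.eye(F), HA.T).T
            GC = (B.T @ B) * (A.T @ A)
            HC = np.einsum("kfj,fg,jg->kg", Y, B, A)
            if self.nonneg_concentrations:
                C = _hals_update(C, GC, HC, rng)
            else:
                C = np.linalg.solve(GC + _EPS * np.eye(F), HC.T).T
            Zhat = np.einsum("fg,kg,jg->kfj", B, C, A)
            loss = float(proj_loss.sum() + np.sum((Y - Zhat) ** 2))
            history.append(loss)
            if loss_prev - loss <= tol * max(total_ss, loss_prev) and it > 0:
                converged = True
                loss_prev = loss
                break
            loss_prev = loss
        return {"A": A, "B": B, "C": C, "P": P, "loss": loss_prev,
                "history": history, "converged": converged,
                "n_iter": len(history)}

    def _fit_flexible(self, *, seed, tol, max_iter):
        """Flexible-coupling variant: non-negative B_k with an increasing
        quadratic penalty toward the coupled form P_k B."""
        X = self.tensor.slabs
        K, F, J = len(X), self.n_components, self.tensor.n_mz
        rng = rng_stream(seed, "parafac2-flex")
        A = np.abs(np.linalg.eigh(sum(Xk.T @ Xk for Xk in X))[1][:, ::-1][:, :F])
        C = np.ones((K, F))
        Bks = [np.abs(rng.standard_normal((Xk.shape[0], F))) for Xk in X]
        Bc = np.eye(F)
        P = [None] * K
        total_ss = self.tensor.total_ss()
        mu = 1e-4 * total_ss / K
        history = []
        loss_prev = np.inf
        converged = False
        for it in range(max_iter):
            for k in range(K):
                U, _, Vt = np.linalg.svd(Bks[k] @ Bc.T, full_matrices=False)
                P[k] = U @ Vt
            Bc = sum(P[k].T @ Bks[k] for k in range(K)) / K
            AtA = A.T @ A
            for k, Xk in enumerate(X):
                D = np.diag(C[k])
                Gk = D @ AtA @ D + mu * np.eye(F)
                Hk = Xk @ A @ D + mu * P[k] @ Bc
                Bks[k] = _hals_update(Bks[k], Gk, Hk, rng)
            GA = sum(np.outer(C[k], C[k]) * (Bks[k].T @ Bks[k]) for k in range(K))
            HA = sum(Xk.T @ Bks[k] * C[k] for k, Xk in enumerate(X))
            A = _hals_update(A, GA, HA, rng)
            for k, Xk in enumerate(X):
                Gk = (Bks[k].T @ Bks[k]) * (A.T @ A)
                Hk = np.diag(Bks[k].T @ Xk @ A)[None, :]
                C[k : k + 1] = _hals_update(C[k : k + 1].copy(), Gk, Hk, rng)
            sse = sum(
                np.sum((Xk - Bks[k] @ np.diag(C[k]) @ A.T) ** 2)
                for k, Xk in enumerate(X)
            )
            history.append(float(sse))
            if abs(loss_prev - sse) <= tol * max(total_ss, 1.0) and it > 10:
                converged = True
                break
            loss_prev = sse
            mu = min(mu * 1.05, total_ss)
        state = {"A": A, "B": Bc, "C": C, "P": P, "loss": float(sse),
                 "history": history, "converged": converged,
                 "n_iter": len(history), "Bks": Bks}
        return self._finalize(state, total_ss, [float(sse)])

    def _finalize(self, state, total_ss, restart_losses) -> "Parafac2Results":
        A, B, C, P = state["A"], state["B"], state["C"], state["P"]
        # unit-norm spectra and elution shapes; scale lives in C
        a_norm = np.linalg.norm(A, axis=0)
        a_norm[a_norm == 0] = 1.0
        b_norm = np.linalg.norm(B, axis=0)
        b_norm[b_norm == 0] = 1.0
        A = A / a_norm
        B = B / b_norm
        C = C * a_norm * b_norm
        order = np.argsort(-np.linalg.norm(C, axis=0), kind="stable")
        A, B, C = A[:, order], B[:, order], C[:, order]
        if "Bks" in state:
            profiles = [Bk[:, order] / (a_norm * b_norm)[order] for Bk in state["Bks"]]
        else:
            profiles = [Pk @ B for Pk in P]
        factors = Parafac2Factors(spectra=A, elution_profiles=profiles,
                                  concentrations=C)
        fit_percent = 100.0 * (1.0 - state["loss"] / total_ss)
        return Parafac2Results(
            model=self, factors=factors, coupling=B, projections=P,
            fit_percent=float(fit_percent), n_iterations=state["n_iter"],
            converged=bool(state["converged"]),
            loss_history=np.asarray(state["history"]),
            restart_losses=list(map(float, restart_losses)),
        )


@dataclass
class Parafac2Results:
    """Fitted PARAFAC2 model: factors, projections and diagnostics."""

    model: Parafac2
    factors: Parafac2Factors
    coupling: np.ndarray  # F x F cross-product root, B_k = P_k B
    projections: list
    fit_percent: float
    n_iterations: int
    converged: bool
    loss_history: np.ndarray
    restart_losses: list = field(default_factory=list)

    @property
    def spectra(self) -> np.ndarray:
        return self.factors.spectra

    @property
    def concentrations(self) -> np.ndarray:
        return self.factors.concentrations

    @property
    def elution_profiles(self) -> list[np.ndarray]:
        return self.factors.elution_profiles

    @property
    def n_components(self) -> int:
        return self.factors.n_components

    def reconstruct(self) -> list[np.ndarray]:
        return self.factors.reconstruct()

    def core_consistency(self) -> float:
        return core_consistency(self)

    def apex_retention_times(self) -> np.ndarray:
        """Per-component consensus apex: median over samples of the retention
        time at each elution profile's maximum."""
        rts = np.array(
            [
                [rt[np.argmax(np.abs(Bk[:, f]))] for f in range(self.n_components)]
                for Bk, rt in zip(self.factors.elution_profiles,
                                  self.model.tensor.retention_time_axes)
            ]
        )
        return np.median(rts, axis=0)

    def summary(self) -> str:
        lines = [
            "PARAFAC2 Results",
            "================",
            f"components:        {self.n_components}",
            f"samples (K):       {self.model.tensor.n_samples}",
            f"m/z bins (J):      {self.model.tensor.n_mz}",
            f"fit %:             {self.fit_percent:.4f}",
            f"core consistency:  {self.core_consistency():.2f}",
            f"iterations:        {self.n_iterations}",
            f"converged:         {self.converged}",
            f"cross-product dev: {self.factors.cross_product_deviation():.3e}",
        ]
        return "\n".join(lines)


def fit_parafac2(tensor: ThreeWayTensor, n_components: int, *, seed: int = 0,
                 tol: float = 1e-8, max_iter: int = 2000, n_restarts: int = 10,
                 **kwargs) -> Parafac2Results:
    """Convenience wrapper: build and fit a :class:`Parafac2` model."""
    return Parafac2(tensor, n_components, **kwargs).fit(
        seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts
    )


def core_consistency(results: Parafac2Results,
                     tensor: ThreeWayTensor | None = None) -> float:
    """Core consistency diagnostic (corcondia, ≤ 100) of a fitted model.

    The PARAFAC2 slabs are projected onto their elution subspaces
    (``Y_k = P_kᵀ X_k``), which turns the model into a regular trilinear one;
    the least-squares Tucker core of the projected array is then compared to
    the superdiagonal target: ``100·(1 − Σ(g−t)²/Σt²)``.  A one-component
    model is identically 100 (the 1x1x1 core equals the optimal global scale,
    which is 1 at any ALS stationary point), so F=1 short-circuits.
    """
    if tensor is None:
        tensor = results.model.tensor
    F = results.n_components
    if tensor.n_mz != results.spectra.shape[0] or tensor.n_samples != len(
        results.projections
    ):
        raise ValueError("model and tensor dimensions do not match")
    if F == 1:
        return 100.0
    Y = np.stack([Pk.T @ Xk for Pk, Xk in zip(results.projections, tensor.slabs)])
    Bp = np.linalg.pinv(results.coupling)
    Ap = np.linalg.pinv(results.spectra)
    Cp = np.linalg.pinv(results.concentrations)
    G = np.einsum("pf,qj,rk,kfj->pqr", Bp, Ap, Cp, Y)
    T = np.zeros((F, F, F))
    for f in range(F):
        T[f, f, f] = 1.0
    return float(100.0 * (1.0 - np.sum((G - T) ** 2) / F))


@dataclass
class ModelSelectionReport:
    """Fit and core-consistency survey over candidate component counts."""

    records: list
    chosen_F: int
    reliable: bool
    rule: str

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "records": self.records,
                "chosen_F": self.chosen_F,
                "reliable": self.reliable,
                "rule": self.rule,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def select_components(tensor: ThreeWayTensor, f_max: int, *,
                      fit_tolerance_pp: float = 0.5,
                      corcondia_threshold: float = 80.0, seed: int = 0,
                      n_restarts: int = 10, tol: float = 1e-8,
                      max_iter: int = 2000, **kwargs) -> ModelSelectionReport:
    """Choose the number of PARAFAC2 components for an interval.

    Evaluates F = 1..f_max; keeps candidates whose core consistency meets
    ``corcondia_threshold`` and whose fit is within ``fit_tolerance_pp``
    percentage points of the best fit observed — such candidates are fit-wise
    ties — and picks the smallest of them: the most parsimonious model that
    explains (essentially) as much as any other while remaining trilinear-
    consistent.  Adding a component that buys less fit than the tolerance is
    noise-fitting, which is exactly what the core consistency collapse of
    over-factored models signals.  If no F qualifies, the highest-corcondia F
    is returned flagged unreliable, as is the case where no candidate
    converged.
    """
    if f_max < 1:
        raise ValueError("f_max must be >= 1")
    f_max = min(f_max, tensor.min_dimension())
    records = []
    for F in range(1, f_max + 1):
        res = fit_parafac2(tensor, F, seed=seed, n_restarts=n_restarts,
                           tol=tol, max_iter=max_iter, **kwargs)
        records.append(
            {
                "F": F,
                "fit_percent": res.fit_percent,
                "core_consistency": res.core_consistency(),
                "converged": res.converged,
            }
        )
    max_fit = max(r["fit_percent"] for r in records)
    candidates = [
        r["F"]
        for r in records
        if r["core_consistency"] >= corcondia_threshold
        and r["fit_percent"] >= max_fit - fit_tolerance_pp
    ]
    rule = (
        f"smallest F with corcondia >= {corcondia_threshold} and fit within "
        f"{fit_tolerance_pp} pp of max fit {max_fit:.3f}"
    )
    any_converged = any(r["converged"] for r in records)
    if candidates:
        chosen = min(candidates)
        reliable = any_converged
    else:
        chosen = max(records, key=lambda r: r["core_consistency"])["F"]
        reliable = False
        rule += " (no candidate met the rule; fell back to max corcondia)"
    return ModelSelectionReport(records=records, chosen_F=int(chosen),
                                reliable=reliable, rule=rule)
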
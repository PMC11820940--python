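"""Bayesian whole-genome regression models for line selection.

Two models, both with random genetic effects g ~ N(0, sigma_g^2 G) where G
is a genomic relationship kernel:

* :class:`GBLUP` — Gaussian response ``y_i = mu + g_i + e_i`` with
  ``e_i ~ N(0, sigma^2)``; the standard genomic BLUP regression fitted by
  Gibbs sampling.
* :class:`ProbitGBLUP` — binary response through a latent liability
  ``l_i = beta0 + g_i + e_i`` with ``e_i ~ N(0, 1)`` fixed; the observed
  class is 1 iff ``l_i > 0``.  beta0 carries a flat prior.

Both samplers work on the training block of G only: with the
eigendecomposition ``G_tt = U D U'`` the rotated effects ``b = U'g_train``
have independent conditional posteriors (U is orthogonal on that block), so
one sweep costs O(n) for the Gaussian model after an O(n^3) decomposition
done once per fit.  Masked (test) lines contribute no likelihood and are
predicted through the conditional mean ``G_st G_tt^{-1} g_train`` — the same
posterior a full-vector or response-imputation scheme would give.

Variance components carry scaled-inverse-chi-squared priors (df = 5, scale
splitting the sample variance of y 50/50 between genetic and residual).
:func:`blup_closed_form` provides the deterministic fixed-variance BLUP used
as an independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .grm import GenomicRelationship

__all__ = [
    "MCMCSettings",
    "GBLUP",
    "ProbitGBLUP",
    "GBLUPResults",
    "ProbitResults",
    "fit_gblup",
    "fit_probit",
    "blup_closed_form",
    "effective_sample_size",
]

_PRIOR_DF = 5.0
_PRIOR_R2 = 0.5  # prior split of phenotypic variance between genetic and residual
_MIN_TRAIN = 20
_EIG_FLOOR = -1e-8


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs sampler control.  The seed is mandatory — never defaulted."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("MCMCSettings.seed is mandatory")
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS via Geyer's initial-positive-sequence estimator."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / max(tau, 1e-12)))


def _as_grm(G, line_ids=None) -> GenomicRelationship:
    if isinstance(G, GenomicRelationship):
        return G
    G = np.asarray(G, dtype=float)
    if line_ids is None:
        line_ids = [f"L{i:04d}" for i in range(G.shape[0])]
    return GenomicRelationship(list(line_ids), G)


def _masked_bool(masked, line_ids) -> np.ndarray:
    n = len(line_ids)
    if masked is None:
        return np.zeros(n, dtype=bool)
    masked = np.asarray(masked)
    if masked.dtype == bool:
        if masked.shape != (n,):
            raise ValueError("boolean mask length mismatch")
        return masked.copy()
    pos = {lid: i for i, lid in enumerate(line_ids)}
    out = np.zeros(n, dtype=bool)
    for lid in masked:
        out[pos[lid]] = True
    return out


class _EigenBasis:
    """Shared train-block eigen machinery for both samplers."""

    def __init__(self, G: np.ndarray, train: np.ndarray, test: np.ndarray):
        G_tt = G[np.ix_(train, train)]
        d, U = np.linalg.eigh(G_tt)
        if d[0] < _EIG_FLOOR:
            raise ValueError(
                f"G is not positive semi-definite on the training block "
                f"(min eigenvalue {d[0]:.3e}); apply grm.stabilize first"
            )
        keep = d > max(d[-1], 1.0) * 1e-12
        self.d = np.clip(d[keep], 1e-300, None)
        self.U = U[:, keep]
        self.r = int(self.d.size)
        self.n_t = int(train.sum())
        self.Ut1 = self.U.sum(axis=0)
        self.mean_diag = float(np.mean(np.diag(G_tt)))
        if test.any():
            V = G[np.ix_(test, train)] @ self.U  # (n_s, r)
            self.Amat = V / self.d
            C0 = G[np.ix_(test, test)] - self.Amat @ V.T
            C0 = (C0 + C0.T) / 2.0 + 1e-8 * np.eye(C0.shape[0])
            self.L0 = np.linalg.cholesky(C0)
        else:
            self.Amat = np.zeros((0, self.r))
            self.L0 = np.zeros((0, 0))


class _ResultsBase:
    """Prediction/fitted-value access shared by both Results classes."""

    line_ids: list[str]
    masked: np.ndarray
    _scores: np.ndarray        # per-line score, NaN where undefined
    _fitted: np.ndarray        # in-sample score for train lines

    def predict(self, line_ids) -> pd.Series:
        """Scores for masked (test) lines; requesting a training line errors."""
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        idx = []
        for lid in line_ids:
            if lid not in pos:
                raise KeyError(f"unknown line {lid!r}")
            i = pos[lid]
            if not self.masked[i]:
                raise ValueError(
                    f"line {lid!r} was not masked at fit time; use "
                    "fitted_values() for explicit in-sample scores"
                )
            idx.append(i)
        return pd.Series(self._scores[idx], index=list(line_ids))

    @property
    def predictions(self) -> pd.Series:
        ids = [lid for lid, m in zip(self.line_ids, self.masked) if m]
        return pd.Series(self._scores[self.masked], index=ids)

    def fitted_values(self) -> pd.Series:
        """In-sample scores for the training (unmasked) lines."""
        ids = [lid for lid, m in zip(self.line_ids, self.masked) if not m]
        return pd.Series(self._fitted, index=ids)


@dataclass
class GBLUPResults(_ResultsBase):
    """Posterior summaries of a GBLUP fit.

    ``predictions`` are posterior means of mu + g_i for masked lines.
    """

    line_ids: list[str]
    masked: np.ndarray
    mu_hat: float
    g_hat: pd.Series
    sigma2_g_hat: float
    sigma2_e_hat: float
    settings: MCMCSettings
    chains: dict = field(repr=False, default_factory=dict)
    _scores: np.ndarray = field(repr=False, default=None)
    _fitted: np.ndarray = field(repr=False, default=None)

    @property
    def heritability(self) -> float:
        return self.sigma2_g_hat / (self.sigma2_g_hat + self.sigma2_e_hat)

    @property
    def ess(self) -> dict[str, float]:
        return {k: effective_sample_size(v) for k, v in self.chains.items()}

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, est in [
            ("mu", self.mu_hat),
            ("sigma2_g", self.sigma2_g_hat),
            ("sigma2_e", self.sigma2_e_hat),
            ("h2", self.heritability),
        ]:
            chain = self.chains.get(name)
            rows.append({
                "parameter": name,
                "post_mean": est,
                "post_sd": float(np.std(chain)) if chain is not None else np.nan,
                "ess": effective_sample_size(chain) if chain is not None else np.nan,
            })
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        """Per-line export: g_hat and prediction/fitted score."""
        return pd.DataFrame({
            "line_id": self.line_ids,
            "g_hat": self.g_hat.to_numpy(),
            "masked": self.masked,
            "score": self._scores,
        })


@dataclass
class ProbitResults(_ResultsBase):
    """Posterior summaries of a probit threshold-model fit.

    ``predictions`` are posterior means of Phi(beta0 + g_i) for masked lines
    (probabilities of being a top line).  The residual liability variance is
    fixed at 1, not estimated.
    """

    line_ids: list[str]
    masked: np.ndarray
    beta0_hat: float
    g_hat: pd.Series
    sigma2_g_hat: float
    settings: MCMCSettings
    chains: dict = field(repr=False, default_factory=dict)
    _scores: np.ndarray = field(repr=False, default=None)
    _fitted: np.ndarray = field(repr=False, default=None)

    @property
    def probabilities(self) -> pd.Series:
        return self.predictions

    @property
    def ess(self) -> dict[str, float]:
        return {k: effective_sample_size(v) for k, v in self.chains.items()}

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, est in [("beta0", self.beta0_hat), ("sigma2_g", self.sigma2_g_hat)]:
            chain = self.chains.get(name)
            rows.append({
                "parameter": name,
                "post_mean": est,
                "post_sd": float(np.std(chain)) if chain is not None else np.nan,
                "ess": effective_sample_size(chain) if chain is not None else np.nan,
            })
        return pd.DataFrame(rows).set_index("parameter")


class GBLUP:
    """Gaussian GBLUP model ``y = mu + g + e`` built from data.

    Parameters
    ----------
    y : array-like, length n
        Responses aligned with the relationship matrix; entries for masked
        lines may be NaN.
    G : GenomicRelationship or ndarray
    masked : boolean array or iterable of line ids
        Test lines: excluded from the likelihood, predicted through G.
    """

    def __init__(self, y, G, masked=None, line_ids=None):
        self.grm = _as_grm(G, line_ids)
        self.line_ids = list(self.grm.line_ids)
        self.y = np.asarray(y, dtype=float)
        if self.y.shape != (len(self.line_ids),):
            raise ValueError("y length does not match G")
        self.masked = _masked_bool(masked, self.line_ids)
        train = ~self.masked
        if np.isnan(self.y[train]).any():
            raise ValueError("unmasked responses contain NaN")

    @classmethod
    def from_dataframe(cls, phenotypes, grm: GenomicRelationship,
                       environment: str, trait: str) -> "GBLUP":
        """Build from a PhenotypeTable slice; lines without a phenotype for
        this (environment, trait) are masked."""
        rec = phenotypes.slice(environment, trait)
        vals = dict(zip(rec["line_id"], rec["value"]))
        y = np.array([vals.get(lid, np.nan) for lid in grm.line_ids])
        masked = np.isnan(y)
        return cls(y, grm, masked=masked)

    def fit(self, settings: MCMCSettings, fix_variances: tuple[float, float] | None = None,
            fix_mu: float | None = None) -> GBLUPResults:
        train = ~self.masked
        n_t = int(train.sum())
        if fix_variances is None and n_t < _MIN_TRAIN:
            raise ValueError(f"need >= {_MIN_TRAIN} unmasked lines to estimate variances (got {n_t})")
        if n_t < 2:
            raise ValueError("need at least 2 unmasked lines")
        basis = _EigenBasis(self.grm.G, train, self.masked)
        y_t = self.y[train]
        rng = np.random.default_rng(settings.seed)

        Uty = basis.U.T @ y_t
        Ut1 = basis.Ut1
        d = basis.d
        sum_y, yy = float(y_t.sum()), float(y_t @ y_t)
        s2y = float(np.var(y_t, ddof=1)) if n_t > 1 else 1.0
        s2y = max(s2y, 1e-12)
        S_e = _PRIOR_R2 * s2y * (_PRIOR_DF + 2) / _PRIOR_DF
        S_g = _PRIOR_R2 * s2y * (_PRIOR_DF + 2) / _PRIOR_DF / max(basis.mean_diag, 1e-12)

        if fix_variances is not None:
            sg2, se2 = map(float, fix_variances)
            if se2 <= 0:
                raise ValueError("residual variance must be positive")
        else:
            sg2, se2 = _PRIOR_R2 * s2y / max(basis.mean_diag, 1e-12), _PRIOR_R2 * s2y
        mu = float(np.mean(y_t)) if fix_mu is None else float(fix_mu)
        b = np.zeros(basis.r)

        kept = 0
        b_sum = np.zeros(basis.r)
        mu_draws = np.empty(settings.n_kept)
        sg2_draws = np.empty(settings.n_kept)
        se2_draws = np.empty(settings.n_kept)

        for it in range(settings.n_iter):
            t = Uty - mu * Ut1
            if sg2 <= 0:
                b[:] = 0.0
            else:
                prec = 1.0 / se2 + 1.0 / (sg2 * d)
                b = t / se2 / prec + rng.standard_normal(basis.r) / np.sqrt(prec)
            if fix_mu is None:
                mu = rng.normal((sum_y - Ut1 @ b) / n_t, np.sqrt(se2 / n_t))
            if fix_variances is None:
                t = Uty - mu * Ut1
                sse = yy - 2 * mu * sum_y + n_t * mu * mu - 2 * (t @ b) + b @ b
                se2 = (_PRIOR_DF * S_e + max(sse, 0.0)) / rng.chisquare(_PRIOR_DF + n_t)
                ssg = float(np.sum(b * b / d))
                sg2 = (_PRIOR_DF * S_g + ssg) / rng.chisquare(_PRIOR_DF + basis.r)
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                b_sum += b
                mu_draws[kept] = mu
                sg2_draws[kept] = sg2
                se2_draws[kept] = se2
                kept += 1

        b_bar = b_sum / kept
        g = np.full(len(self.line_ids), np.nan)
        g[train] = basis.U @ b_bar
        if self.masked.any():
            g[self.masked] = basis.Amat @ b_bar
        mu_hat = float(mu_draws.mean())
        scores = mu_hat + g
        res = GBLUPResults(
            line_ids=self.line_ids,
            masked=self.masked.copy(),
            mu_hat=mu_hat,
            g_hat=pd.Series(g, index=self.line_ids),
            sigma2_g_hat=float(sg2_draws.mean()),
            sigma2_e_hat=float(se2_draws.mean()),
            settings=settings,
            chains={"mu": mu_draws, "sigma2_g": sg2_draws, "sigma2_e": se2_draws},
        )
        res._scores = scores
        res._fitted = scores[train]
        return res


class ProbitGBLUP:
    """Probit threshold model for binary top/non-top labels.

    ``P(Y_b = 1 | g) = Phi(beta0 + g)`` through a latent liability with unit
    residual variance; beta0 has a flat prior.
    """

    def __init__(self, yb, G, masked=None, line_ids=None):
        self.grm = _as_grm(G, line_ids)
        self.line_ids = list(self.grm.line_ids)
        yb = np.asarray(yb, dtype=float)
        if yb.shape != (len(self.line_ids),):
            raise ValueError("label length does not match G")
        self.masked = _masked_bool(masked, self.line_ids)
        train = ~self.masked
        lab = yb[train]
        if np.isnan(lab).any():
            raise ValueError("unmasked labels contain NaN")
        if not np.isin(lab, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        if lab.min() == lab.max():
            raise ValueError("training labels are single-class; liability truncation is degenerate")
        self.yb = yb

    def fit(self, settings: MCMCSettings) -> ProbitResults:
        train = ~self.masked
        n_t = int(train.sum())
        if n_t < _MIN_TRAIN:
            raise ValueError(f"need >= {_MIN_TRAIN} unmasked lines (got {n_t})")
        basis = _EigenBasis(self.grm.G, train, self.masked)
        lab = self.yb[train].astype(bool)
        rng = np.random.default_rng(settings.seed)

        d, U, Ut1 = basis.d, basis.U, basis.Ut1
        S_g = _PRIOR_R2 * (_PRIOR_DF + 2) / _PRIOR_DF / max(basis.mean_diag, 1e-12)
        p1 = float(lab.mean())
        beta0 = float(ndtri(np.clip(p1, 0.01, 0.99)))
        sg2 = _PRIOR_R2 / max(basis.mean_diag, 1e-12)
        b = np.zeros(basis.r)
        n_test = int(self.masked.sum())

        kept = 0
        b_sum = np.zeros(basis.r)
        beta0_draws = np.empty(settings.n_kept)
        sg2_draws = np.empty(settings.n_kept)
        prob_test = np.zeros(n_test)
        prob_train = np.zeros(n_t)

        tiny = 1e-12
        for it in range(settings.n_iter):
            Ub = U @ b
            eta = beta0 + Ub
            # liabilities from truncated normals: l > 0 iff label 1
            plo = np.clip(ndtr(-eta), tiny, 1 - tiny)
            u = rng.uniform(size=n_t)
            q = np.where(lab, plo + u * (1 - plo), u * plo)
            l = eta + ndtri(np.clip(q, tiny, 1 - tiny))
            t = U.T @ l - beta0 * Ut1
            prec = 1.0 + 1.0 / (sg2 * d)
            b = t / prec + rng.standard_normal(basis.r) / np.sqrt(prec)
            beta0 = rng.normal((l.sum() - Ut1 @ b) / n_t, np.sqrt(1.0 / n_t))
            ssg = float(np.sum(b * b / d))
            sg2 = (_PRIOR_DF * S_g + ssg) / rng.chisquare(_PRIOR_DF + basis.r)
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                b_sum += b
                beta0_draws[kept] = beta0
                sg2_draws[kept] = sg2
                prob_train += ndtr(beta0 + U @ b)
                if n_test:
                    g_test = basis.Amat @ b + np.sqrt(sg2) * (basis.L0 @ rng.standard_normal(n_test))
                    prob_test += ndtr(beta0 + g_test)
                kept += 1

        b_bar = b_sum / kept
        g = np.full(len(self.line_ids), np.nan)
        g[train] = U @ b_bar
        if n_test:
            g[self.masked] = basis.Amat @ b_bar
        scores = np.full(len(self.line_ids), np.nan)
        eps = 1e-12
        scores[train] = np.clip(prob_train / kept, eps, 1 - eps)
        if n_test:
            scores[self.masked] = np.clip(prob_test / kept, eps, 1 - eps)
        res = ProbitResults(
            line_ids=self.line_ids,
            masked=self.masked.copy(),
            beta0_hat=float(beta0_draws.mean()),
            g_hat=pd.Series(g, index=self.line_ids),
            sigma2_g_hat=float(sg2_draws.mean()),
            settings=settings,
            chains={"beta0": beta0_draws, "sigma2_g": sg2_draws},
        )
        res._scores = scores
        res._fitted = scores[train]
        return res


def fit_gblup(y, G, settings: MCMCSettings, masked=None, line_ids=None,
              fix_variances=None, fix_mu=None) -> GBLUPResults:
    """Functional wrapper around ``GBLUP(...).fit(...)``."""
    return GBLUP(y, G, masked=masked, line_ids=line_ids).fit(
        settings, fix_variances=fix_variances, fix_mu=fix_mu)


def fit_probit(yb, G, settings: MCMCSettings, masked=None, line_ids=None) -> ProbitResults:
    """Functional wrapper around ``ProbitGBLUP(...).fit(...)``."""
    return ProbitGBLUP(yb, G, masked=masked, line_ids=line_ids).fit(settings)


def blup_closed_form(y, G, sigma2_g: float, sigma2_e: float, masked=None) -> np.ndarray:
    """Deterministic BLUP of g for all lines with known variance components.

    g_hat = sigma_g^2 G[:, train] (sigma_g^2 G_tt + sigma^2 I)^{-1} (y_t - mean(y_t))
    """
    G = G.G if isinstance(G, GenomicRelationship) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = G.shape[0]
    masked = np.zeros(n, dtype=bool) if masked is None else np.asarray(masked, dtype=bool)
    train = ~masked
    if not train.any():
        raise ValueError("unmasked subset is empty")
    if sigma2_e <= 0:
        raise ValueError("residual variance must be positive")
    if sigma2_g == 0.0:
        return np.zeros(n)
    y_t = y[train]
    G_tt = G[np.ix_(train, train)]
    A = sigma2_g * G_tt + sigma2_e * np.eye(int(train.sum()))
    try:
        alpha = np.linalg.solve(A, y_t - y_t.mean())
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular mixed-model system") from exc
    return sigma2_g * (G[:, train] @ alpha)
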
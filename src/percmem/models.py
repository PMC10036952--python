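"""Hierarchical Bayesian models of disambiguation strength vs segment index.

Three model families describe how the selected trials' disambiguation
strength (``bias``) depends on segment index:

* **Hierarchical linear** — per-participant intercepts and slopes with a
  correlated bivariate random effect:

  ``bias_i ~ Normal(alpha_P[i] + beta_P[i] * (seg_i - 1), sigma)``

  with population priors ``alpha, beta ~ Normal(0, 1)``, random-effect
  scales ``sigma_alpha, sigma_beta ~ Exponential(1)``, residual
  ``sigma ~ Exponential(1)`` and an LKJ(2) prior on the 2x2 correlation
  matrix, implemented noncentered via its Cholesky factor.

* **Hierarchical additive** — a smooth curve as a weighted sum of cubic
  B-spline basis functions, scaled per participant:

  ``mu_i = (B @ w_spline)[seg_i] * w_P[i]`` with ``w_spline ~ Normal(0, 1)``,
  strictly positive participant weights ``log w_P ~ Normal(0, sigma_P)``
  (noncentered), a strongly regularizing ``sigma_P ~ Exponential(10)`` that
  keeps the spline weights' sign and magnitude interpretable, and
  ``sigma ~ Exponential(1)``.

* **Dual-condition additive** — the additive model duplicated for two
  conditions (prime perception vs perceptual memory) with per-condition
  participant weights and residual scales; the spline-weight sets are
  *independent*, *correlated* (bivariate normal with correlation ``rho``,
  LKJ(2) prior, noncentered) or *identical* across conditions.

Because the likelihood mean depends on the data only through the
(participant, segment[, condition]) cell, fitting uses exact sufficient
statistics (cell counts, cell means and the pooled within-cell sum of
squares); pointwise log-likelihoods for LOO are reconstructed per
observation on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .intervals import hpdi, percentile_ci
from .sampler import MCMCConfig, diagnostics, run_ensemble
from .splines import SplineBasis
from .triplets import Triplet, average_sequence

__all__ = [
    "CONDITIONS",
    "DUAL_VARIANTS",
    "FitResult",
    "LooResult",
    "segment_observations",
    "dual_observations",
    "fit_hierarchical_linear",
    "fit_additive",
    "fit_dual",
    "loo_elpd",
    "compare_models",
    "weight_contrast_fraction",
]

CONDITIONS = ("perception", "memory")
DUAL_VARIANTS = ("independent", "correlated", "identical")

_LOG2PI = float(np.log(2.0 * np.pi))

# ---------------------------------------------------------------------------
# Observation assembly


def segment_observations(
    per_participant_triplets: dict[str, list[Triplet]],
    selection: str,
    condition: str | None = None,
) -> pd.DataFrame:
    """Long-format observations: one row per (selected triplet, segment).

    Columns: participant, segment_index (1-based), bias and, if requested,
    condition.
    """
    from .triplets import selection_matrix

    frames = []
    for participant, triplets in per_participant_triplets.items():
        values = selection_matrix(triplets, selection)
        n, n_seg = values.shape
        frames.append(
            pd.DataFrame(
                {
                    "participant": np.repeat(participant, n * n_seg),
                    "segment_index": np.tile(np.arange(1, n_seg + 1), n),
                    "bias": values.ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if condition is not None:
        df["condition"] = condition
    return df


def dual_observations(
    per_participant_triplets: dict[str, list[Triplet]],
) -> pd.DataFrame:
    """Observations for the dual-condition fits.

    The ``perception`` condition holds the prime-changed selection and the
    ``memory`` condition the memory-changed selection; triplets in which
    both percepts changed contribute to both conditions, exactly as in the
    triplet-class unions used for the reverse-correlation averages.
    """
    return pd.concat(
        [
            segment_observations(
                per_participant_triplets, "prime_changed", condition="perception"
            ),
            segment_observations(
                per_participant_triplets, "memory_changed", condition="memory"
            ),
        ],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Sufficient statistics


@dataclass(frozen=True)
class _Cells:
    participants: tuple[str, ...]
    n_seg: int
    counts: np.ndarray  # (P, S)
    means: np.ndarray  # (P, S); zero where a cell is empty
    ss_within: float
    n_total: int
    obs_bias: np.ndarray  # (N,)
    obs_p: np.ndarray  # (N,) participant codes
    obs_s: np.ndarray  # (N,) segment codes, 0-based


def _make_cells(df: pd.DataFrame, participants: tuple[str, ...], n_seg: int) -> _Cells:
    bias = df["bias"].to_numpy(dtype=float)
    if not np.all(np.isfinite(bias)):
        raise ValueError("non-finite bias values")
    p_codes = pd.Categorical(
        df["participant"], categories=list(participants)
    ).codes.astype(np.int64)
    if np.any(p_codes < 0):
        raise ValueError("unknown participant label")
    seg = df["segment_index"].to_numpy(dtype=np.int64)
    if seg.min() < 1 or seg.max() > n_seg:
        raise ValueError("segment_index outside [1, n_segments]")
    s_codes = seg - 1
    P, S = len(participants), n_seg
    flat = p_codes * S + s_codes
    counts = np.bincount(flat, minlength=P * S).astype(float)
    sums = np.bincount(flat, weights=bias, minlength=P * S)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    ss_within = float(np.sum((bias - means[flat]) ** 2))
    return _Cells(
        participants=participants,
        n_seg=S,
        counts=counts.reshape(P, S),
        means=means.reshape(P, S),
        ss_within=ss_within,
        n_total=bias.size,
        obs_bias=bias,
        obs_p=p_codes,
        obs_s=s_codes,
    )


def _cell_loglik(mu: np.ndarray, sigma: np.ndarray, cells: _Cells) -> np.ndarray:
    """Total Normal log-likelihood for per-walker cell means mu (W, P, S).

    Overflow in extreme walker positions yields -inf, which the sampler
    treats as a rejected move.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        resid = np.einsum("ps,wps->w", cells.counts, (cells.means - mu) ** 2)
        out = (
            -0.5 * cells.n_total * _LOG2PI
            - cells.n_total * np.log(sigma)
            - (cells.ss_within + resid) / (2.0 * sigma**2)
        )
    return np.where(np.isfinite(out), out, -np.inf)


# ---------------------------------------------------------------------------
# Shared prior pieces (unconstrained coordinates)


def _lp_normal(x: np.ndarray) -> np.ndarray:
    return -0.5 * np.sum(x**2, axis=-1)


def _lp_exponential(log_sigma: np.ndarray, rate: float) -> np.ndarray:
    # Exponential(rate) prior on sigma, sampled as log sigma (with Jacobian).
    return np.log(rate) - rate * np.exp(log_sigma) + log_sigma


def _lp_lkj2_tanh(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # rho = tanh(t); LKJ(2) density on a 2x2 matrix is prop. to (1 - rho^2),
    # and the tanh Jacobian contributes another factor (1 - rho^2).
    rho = np.tanh(t)
    return rho, 2.0 * np.log1p(-(rho**2))


def _bounded(x: np.ndarray, lim: float = 15.0) -> np.ndarray:
    return np.all(np.abs(x) < lim, axis=-1)


# ---------------------------------------------------------------------------
# Fit result container


@dataclass
class FitResult:
    """Posterior draws plus everything needed for summaries and LOO."""

    model: str
    draws: dict[str, np.ndarray] = field(repr=False)  # (chain, draw[, k])
    participants: tuple[str, ...] = ()
    conditions: tuple[str, ...] = ()
    max_rhat: float = np.nan
    rhat: dict[str, float] = field(default_factory=dict, repr=False)
    # Per-condition cell data and fitted cell means / residual scales.
    _cells: dict[str, _Cells] = field(default_factory=dict, repr=False)
    _mu_cells: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _sigma: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_obs(self) -> int:
        return sum(c.n_total for c in self._cells.values())

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Flattened draws with vector parameters expanded per element."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                labels = self._element_labels(name, arr.shape[2])
                for j in range(arr.shape[2]):
                    out[f"{name}[{labels[j]}]"] = arr[:, :, j]
        return out

    def _element_labels(self, name: str, k: int) -> list[str]:
        if "_P" in name and k == len(self.participants):
            return list(self.participants)
        return [str(j + 1) for j in range(k)]

    def summary(self, mass: float = 0.97) -> pd.DataFrame:
        """Per-parameter posterior summary with 97% CI, HPDI and diagnostics."""
        idata = az.from_dict(posterior=self.draws)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rows = []
        for name, arr in self.scalar_draws().items():
            base = name.split("[")[0]
            flat = arr.ravel()
            lo, hi = percentile_ci(flat, mass)
            hlo, hhi = hpdi(flat, mass)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(flat.mean()),
                    "median": float(np.median(flat)),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "hpdi_lo": hlo,
                    "hpdi_hi": hhi,
                    "rhat": float(np.nanmax(rhat[base].values)),
                    "ess_bulk": float(np.nanmin(ess[base].values)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def predicted_curves(self) -> dict[str, np.ndarray]:
        """Posterior-mean predicted curve per condition, shape (P, S)."""
        return {c: self._mu_cells[c].mean(axis=(0, 1)) for c in self._mu_cells}

    def pointwise_loglik(self, max_draws: int = 1000) -> np.ndarray:
        """Pointwise log-likelihood, shape (chain, draw_sub, n_obs).

        Observations are ordered condition-by-condition (in ``conditions``
        order), preserving the row order of the fitted data within each.
        Draws are strided down so chain*draw_sub <= max_draws.
        """
        some = next(iter(self._mu_cells.values()))
        n_chain, n_draw = some.shape[:2]
        stride = max(1, int(np.ceil(n_chain * n_draw / max_draws)))
        blocks = []
        for cond in self.conditions:
            cells = self._cells[cond]
            mu = self._mu_cells[cond][:, ::stride]  # (C, D', P, S)
            sigma = self._sigma[cond][:, ::stride]  # (C, D')
            mu_obs = mu[:, :, cells.obs_p, cells.obs_s]
            resid = cells.obs_bias[None, None, :] - mu_obs
            blocks.append(
                -0.5 * _LOG2PI
                - np.log(sigma)[:, :, None]
                - resid**2 / (2.0 * sigma[:, :, None] ** 2)
            )
        return np.concatenate(blocks, axis=2)


def _finalize(
    fit: FitResult, check_convergence: bool = True
) -> FitResult:
    if check_convergence:
        fit.max_rhat, fit.rhat = diagnostics(fit.draws)
    return fit


# ---------------------------------------------------------------------------
# Hierarchical linear model


def fit_hierarchical_linear(
    data: pd.DataFrame, mcmc_config: MCMCConfig | None = None
) -> FitResult:
    """Fit the correlated random-intercept/random-slope linear model."""
    # The random-effect correlation mixes slowest; its default chains are
    # longer than the additive models'.
    config = mcmc_config or MCMCConfig(n_steps=100_000, thin=200)
    if len(data) == 0:
        raise ValueError("empty data")
    participants = tuple(sorted(data["participant"].unique()))
    if len(participants) < 2:
        raise ValueError("random effects need at least 2 participants")
    n_seg = int(data["segment_index"].max())
    if data["segment_index"].nunique() < 2:
        raise ValueError("need at least 2 segment levels")
    cells = _make_cells(data, participants, n_seg)
    P = len(participants)
    seg0 = np.arange(n_seg, dtype=float)  # Int - 1

    # x = [alpha, beta, t_rho, log s_alpha, log s_beta, log sigma, zA(P), zB(P)]
    ndim = 6 + 2 * P

    def unpack(x):
        alpha, beta, t_rho = x[:, 0], x[:, 1], x[:, 2]
        s_alpha, s_beta, sigma = np.exp(x[:, 3]), np.exp(x[:, 4]), np.exp(x[:, 5])
        zA, zB = x[:, 6 : 6 + P], x[:, 6 + P :]
        rho = np.tanh(t_rho)
        alpha_P = alpha[:, None] + s_alpha[:, None] * zA
        beta_P = beta[:, None] + s_beta[:, None] * (
            rho[:, None] * zA + np.sqrt(1.0 - rho[:, None] ** 2) * zB
        )
        return alpha, beta, t_rho, s_alpha, s_beta, sigma, rho, alpha_P, beta_P

    def log_prob(x):
        x = np.atleast_2d(x)
        ok = _bounded(x)
        lp = np.full(x.shape[0], -np.inf)
        if not np.any(ok):
            return lp
        xo = x[ok]
        alpha, beta, t_rho, s_a, s_b, sigma, rho, alpha_P, beta_P = unpack(xo)
        prior = (
            -0.5 * (alpha**2 + beta**2)
            + _lp_lkj2_tanh(t_rho)[1]
            + _lp_exponential(xo[:, 3], 1.0)
            + _lp_exponential(xo[:, 4], 1.0)
            + _lp_exponential(xo[:, 5], 1.0)
            + _lp_normal(xo[:, 6:])
        )
        mu = alpha_P[:, :, None] + beta_P[:, :, None] * seg0[None, None, :]
        lp[ok] = prior + _cell_loglik(mu, sigma, cells)
        return lp

    init = np.zeros(ndim)
    init[5] = np.log(max(float(data["bias"].std()), 0.05))
    init[3] = init[4] = np.log(0.1)
    chain = run_ensemble(log_prob, ndim, config, init)

    flat = chain.reshape(-1, ndim)
    _, _, _, s_a, s_b, sigma, rho, alpha_P, beta_P = unpack(flat)
    shape2 = chain.shape[:2]
    draws = {
        "alpha": chain[:, :, 0],
        "beta": chain[:, :, 1],
        "sigma_alpha": s_a.reshape(shape2),
        "sigma_beta": s_b.reshape(shape2),
        "sigma": sigma.reshape(shape2),
        "rho": rho.reshape(shape2),
        "alpha_P": alpha_P.reshape(*shape2, P),
        "beta_P": beta_P.reshape(*shape2, P),
    }
    mu_cells = (
        draws["alpha_P"][..., None] + draws["beta_P"][..., None] * seg0
    )
    fit = FitResult(
        model="hierarchical_linear",
        draws=draws,
        participants=participants,
        conditions=("all",),
        _cells={"all": cells},
        _mu_cells={"all": mu_cells},
        _sigma={"all": draws["sigma"]},
    )
    return _finalize(fit)


# ---------------------------------------------------------------------------
# Hierarchical additive model


def _check_basis(basis: SplineBasis, n_seg: int) -> None:
    if basis.n_points != n_seg:
        raise ValueError(
            f"basis has {basis.n_points} rows but data spans {n_seg} segments"
        )


def _ls_weights(basis: SplineBasis, target: np.ndarray) -> np.ndarray:
    w, *_ = np.linalg.lstsq(basis.matrix, target, rcond=None)
    return w


def fit_additive(
    data: pd.DataFrame,
    basis: SplineBasis,
    mcmc_config: MCMCConfig | None = None,
) -> FitResult:
    """Fit the additive model with positive participant scaling weights."""
    config = mcmc_config or MCMCConfig()
    if len(data) == 0:
        raise ValueError("empty data")
    participants = tuple(sorted(data["participant"].unique()))
    n_seg = int(data["segment_index"].max())
    _check_basis(basis, n_seg)
    cells = _make_cells(data, participants, n_seg)
    P, K = len(participants), basis.n_splines
    B = basis.matrix

    # x = [w(K), log sigma_P, log sigma, z(P)]
    ndim = K + 2 + P

    def unpack(x):
        w = x[:, :K]
        sigma_P, sigma = np.exp(x[:, K]), np.exp(x[:, K + 1])
        z = x[:, K + 2 :]
        w_P = np.exp(sigma_P[:, None] * z)
        return w, sigma_P, sigma, w_P

    def log_prob(x):
        x = np.atleast_2d(x)
        ok = _bounded(x)
        lp = np.full(x.shape[0], -np.inf)
        if not np.any(ok):
            return lp
        xo = x[ok]
        w, sigma_P, sigma, w_P = unpack(xo)
        prior = (
            _lp_normal(w)
            + _lp_exponential(xo[:, K], 10.0)
            + _lp_exponential(xo[:, K + 1], 1.0)
            + _lp_normal(xo[:, K + 2 :])
        )
        curve = w @ B.T  # (W, S)
        mu = curve[:, None, :] * w_P[:, :, None]  # (W, P, S)
        lp[ok] = prior + _cell_loglik(mu, sigma, cells)
        return lp

    pooled = np.where(
        cells.counts.sum(axis=0) > 0,
        np.divide(
            (cells.counts * cells.means).sum(axis=0),
            np.maximum(cells.counts.sum(axis=0), 1.0),
        ),
        0.0,
    )
    init = np.zeros(ndim)
    init[:K] = _ls_weights(basis, pooled)
    init[K] = np.log(0.1)
    init[K + 1] = np.log(max(float(data["bias"].std()), 0.05))
    chain = run_ensemble(log_prob, ndim, config, init)

    flat = chain.reshape(-1, ndim)
    w, sigma_P, sigma, w_P = unpack(flat)
    shape2 = chain.shape[:2]
    draws = {
        "w_spline": w.reshape(*shape2, K),
        "sigma_P": sigma_P.reshape(shape2),
        "sigma": sigma.reshape(shape2),
        "w_P": w_P.reshape(*shape2, P),
    }
    curve = np.einsum("cdk,sk->cds", draws["w_spline"], B)
    mu_cells = curve[:, :, None, :] * draws["w_P"][..., None]
    fit = FitResult(
        model="additive",
        draws=draws,
        participants=participants,
        conditions=("all",),
        _cells={"all": cells},
        _mu_cells={"all": mu_cells},
        _sigma={"all": draws["sigma"]},
    )
    return _finalize(fit)


# ---------------------------------------------------------------------------
# Dual-condition additive model


def fit_dual(
    data: pd.DataFrame,
    basis: SplineBasis,
    variant: str,
    mcmc_config: MCMCConfig | None = None,
) -> FitResult:
    """Fit the two-condition additive model.

    ``variant`` selects how the two spline-weight vectors relate:
    ``independent``, ``correlated`` (bivariate normal with correlation
    ``rho``) or ``identical``.  All other parameters (participant weights,
    residual scales) are duplicated per condition.
    """
    if variant not in DUAL_VARIANTS:
        raise ValueError(f"unknown dual variant {variant!r}")
    config = mcmc_config or MCMCConfig(n_steps=60_000, thin=120)
    if "condition" not in data.columns:
        raise ValueError("dual fits need a 'condition' column")
    present = set(data["condition"].unique())
    if present != set(CONDITIONS):
        raise ValueError(f"need both conditions {CONDITIONS}, got {sorted(present)}")
    participants = tuple(sorted(data["participant"].unique()))
    n_seg = int(data["segment_index"].max())
    _check_basis(basis, n_seg)
    P, K = len(participants), basis.n_splines
    B = basis.matrix
    cells = {
        cond: _make_cells(
            data[data["condition"] == cond], participants, n_seg
        )
        for cond in CONDITIONS
    }

    # Layout: weight block, then per condition [log sigma_P, log sigma, z(P)].
    n_w = {"independent": 2 * K, "correlated": 2 * K + 1, "identical": K}[variant]
    ndim = n_w + 2 * (2 + P)

    def unpack_weights(x):
        if variant == "independent":
            return x[:, :K], x[:, K : 2 * K], None, 0.0
        if variant == "identical":
            return x[:, :K], x[:, :K], None, 0.0
        u, v, t_rho = x[:, :K], x[:, K : 2 * K], x[:, 2 * K]
        rho, lp_rho = _lp_lkj2_tanh(t_rho)
        w_b = rho[:, None] * u + np.sqrt(1.0 - rho[:, None] ** 2) * v
        return u, w_b, rho, lp_rho

    def unpack_condition(x, j):
        off = n_w + j * (2 + P)
        sigma_P = np.exp(x[:, off])
        sigma = np.exp(x[:, off + 1])
        z = x[:, off + 2 : off + 2 + P]
        w_P = np.exp(sigma_P[:, None] * z)
        return sigma_P, sigma, w_P, off

    def log_prob(x):
        x = np.atleast_2d(x)
        ok = _bounded(x)
        lp = np.full(x.shape[0], -np.inf)
        if not np.any(ok):
            return lp
        xo = x[ok]
        w_a, w_b, rho, lp_rho = unpack_weights(xo)
        if variant == "correlated":
            prior = _lp_normal(xo[:, :K]) + _lp_normal(xo[:, K : 2 * K]) + lp_rho
        elif variant == "independent":
            prior = _lp_normal(xo[:, : 2 * K])
        else:
            prior = _lp_normal(xo[:, :K])
        total = prior
        for j, (cond, w) in enumerate(zip(CONDITIONS, (w_a, w_b))):
            sigma_P, sigma, w_P, off = unpack_condition(xo, j)
            total = (
                total
                + _lp_exponential(xo[:, off], 10.0)
                + _lp_exponential(xo[:, off + 1], 1.0)
                + _lp_normal(xo[:, off + 2 : off + 2 + P])
            )
            curve = w @ B.T
            mu = curve[:, None, :] * w_P[:, :, None]
            total = total + _cell_loglik(mu, sigma, cells[cond])
        lp[ok] = total
        return lp

    # Initialise weights from least squares on pooled per-condition means.
    init = np.zeros(ndim)
    pooled = {}
    for cond in CONDITIONS:
        c = cells[cond]
        tot = np.maximum(c.counts.sum(axis=0), 1.0)
        pooled[cond] = (c.counts * c.means).sum(axis=0) / tot
    if variant == "identical":
        init[:K] = _ls_weights(basis, 0.5 * (pooled["perception"] + pooled["memory"]))
    else:
        init[:K] = _ls_weights(basis, pooled["perception"])
        init[K : 2 * K] = _ls_weights(basis, pooled["memory"])
    for j, cond in enumerate(CONDITIONS):
        off = n_w + j * (2 + P)
        init[off] = np.log(0.1)
        init[off + 1] = np.log(
            max(float(data.loc[data["condition"] == cond, "bias"].std()), 0.05)
        )
    chain = run_ensemble(log_prob, ndim, config, init)

    flat = chain.reshape(-1, ndim)
    shape2 = chain.shape[:2]
    w_a, w_b, rho, _ = unpack_weights(flat)
    draws: dict[str, np.ndarray] = {
        "w_spline_perception": w_a.reshape(*shape2, K),
        "w_spline_memory": w_b.reshape(*shape2, K),
    }
    if rho is not None:
        draws["rho"] = rho.reshape(shape2)
    mu_cells, sig = {}, {}
    for j, cond in enumerate(CONDITIONS):
        sigma_P, sigma, w_P, _ = unpack_condition(flat, j)
        draws[f"sigma_P_{cond}"] = sigma_P.reshape(shape2)
        draws[f"sigma_{cond}"] = sigma.reshape(shape2)
        draws[f"w_P_{cond}"] = w_P.reshape(*shape2, P)
        curve = np.einsum(
            "cdk,sk->cds", draws[f"w_spline_{cond}"], B
        )
        mu_cells[cond] = curve[:, :, None, :] * draws[f"w_P_{cond}"][..., None]
        sig[cond] = draws[f"sigma_{cond}"]
    fit = FitResult(
        model=f"dual_{variant}",
        draws=draws,
        participants=participants,
        conditions=CONDITIONS,
        _cells=cells,
        _mu_cells=mu_cells,
        _sigma=sig,
    )
    return _finalize(fit)


def weight_contrast_fraction(
    fit: FitResult, smaller: str = "memory", larger: str = "perception"
) -> dict[str, float]:
    """Per-participant fraction of posterior draws with w_P[smaller] < w_P[larger].

    With the identical-weights model this is the posterior probability that
    the condition needs a gentler version of the shared curve.
    """
    a = fit.draws[f"w_P_{smaller}"]
    b = fit.draws[f"w_P_{larger}"]
    frac = (a < b).mean(axis=(0, 1))
    return dict(zip(fit.participants, map(float, frac)))


# ---------------------------------------------------------------------------
# LOO / ELPD model comparison


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    loo_i: np.ndarray = field(repr=False)  # (n_obs,)
    pareto_k: np.ndarray = field(repr=False)
    n_obs: int = 0


def loo_elpd(fit: FitResult, max_draws: int = 1000) -> LooResult:
    """PSIS-smoothed leave-one-out expected log predictive density."""
    ll = fit.pointwise_loglik(max_draws=max_draws)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    n_draw_sub = ll.shape[1]
    posterior = {
        name: arr[:, :: max(1, arr.shape[1] // n_draw_sub)][:, :n_draw_sub]
        for name, arr in fit.draws.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=posterior, log_likelihood={"bias": ll})
        res = az.loo(idata, pointwise=True)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        loo_i=np.asarray(res.loo_i.values, dtype=float).ravel(),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float).ravel(),
        n_obs=int(res.n_data_points),
    )


def compare_models(loos: dict[str, LooResult]) -> pd.DataFrame:
    """ELPD comparison table: delta vs best, difference SEs, softmax weights.

    The difference SE uses the paired pointwise values,
    ``sqrt(n * var(loo_i_model - loo_i_best))``; relative weights are the
    pseudo-BMA softmax ``exp(elpd_k - max) / sum_j exp(elpd_j - max)``.
    """
    if len(loos) < 2:
        raise ValueError("need at least 2 models to compare")
    sizes = {r.n_obs for r in loos.values()}
    if len(sizes) != 1:
        raise ValueError("models were fitted to different observation sets")
    names = sorted(loos, key=lambda k: loos[k].elpd, reverse=True)
    best = loos[names[0]]
    elpds = np.array([loos[k].elpd for k in names])
    weights = np.exp(elpds - elpds.max())
    weights /= weights.sum()
    rows = []
    for name, weight in zip(names, weights):
        r = loos[name]
        diff = r.loo_i - best.loo_i
        rows.append(
            {
                "model": name,
                "elpd": r.elpd,
                "se": r.se,
                "delta_elpd": r.elpd - best.elpd,
                "delta_se": float(np.sqrt(diff.size * diff.var())),
                "weight": float(weight),
            }
        )
    return pd.DataFrame(rows).set_index("model")
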
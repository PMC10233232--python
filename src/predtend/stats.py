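"""Per-voxel Bayesian multilevel regression of cortical tracking.

For every voxel, encoding accuracy (Pearson r) is regressed on the number
of distractor speakers (0-2, continuous), the zero-centred prediction
tendency and their interaction — optionally fully crossed with binary word
surprisal — with a random intercept per subject and a Student-T response
distribution:

    tracking ~ n_distractors * prediction_tendency + (1 | subject)

The model uses weakly informative, data-scaled normal priors on the
fixed effects, half-normal priors on the group and residual scales and a
broad gamma prior on the Student-T degrees of freedom.  It is sampled by
a scale-mixture Gibbs sampler (the Student-T written as a normal with a
latent gamma precision per observation), which gives exact conjugate
draws for all location parameters and slice updates for the scales;
r-hat and effective sample size come from arviz.  A coefficient is significant when its 94% highest
density interval excludes zero; significant voxels additionally need at
least two significant grid neighbours, and posterior draws are pooled over
the connected components ("clusters") that survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MAIN_TERMS = ["Intercept", "n_distractors", "prediction_tendency", "n_distractors:prediction_tendency"]
SURPRISAL_TERMS = [
    "Intercept",
    "n_distractors",
    "word_surprisal",
    "prediction_tendency",
    "n_distractors:word_surprisal",
    "n_distractors:prediction_tendency",
    "word_surprisal:prediction_tendency",
    "n_distractors:word_surprisal:prediction_tendency",
]


def prepare_table(table: pd.DataFrame, formula: str = "main") -> pd.DataFrame:
    """Validate and centre a regression table (one or many voxels).

    Requires columns subject_id, tracking, n_distractors,
    prediction_tendency (plus word_surprisal for the surprisal formula);
    prediction_tendency is zero-centred across subjects.
    """
    required = {"subject_id", "tracking", "n_distractors", "prediction_tendency"}
    if formula == "surprisal":
        required |= {"word_surprisal"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"regression table lacks columns: {sorted(missing)}")
    t = table.copy()
    if t[sorted(required)].isna().any().any():
        raise ValueError("regression table contains missing values in fitted factors")
    if np.any(np.abs(t["tracking"]) > 1 + 1e-9):
        raise ValueError("tracking values must lie in [-1, 1]")
    # centre per subject-level value, not per row, so unbalanced cells do not shift it
    subj_means = t.groupby("subject_id")["prediction_tendency"].first()
    t["prediction_tendency"] = t["prediction_tendency"] - subj_means.mean()
    return t


def _design(table: pd.DataFrame, formula: str, extra_covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    nd = table["n_distractors"].to_numpy(dtype=float)
    pt = table["prediction_tendency"].to_numpy(dtype=float)
    if formula == "main":
        cols = [np.ones(len(table)), nd, pt, nd * pt]
        names = list(MAIN_TERMS)
    elif formula == "surprisal":
        ws = table["word_surprisal"].to_numpy(dtype=float)
        cols = [np.ones(len(table)), nd, ws, pt, nd * ws, nd * pt, ws * pt, nd * ws * pt]
        names = list(SURPRISAL_TERMS)
    else:
        raise ValueError("formula must be 'main' or 'surprisal'")
    for cov in extra_covariates:
        cols.append(table[cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


@dataclass
class PosteriorFit:
    """Posterior draws (chain x draw) per parameter plus diagnostics."""

    draws: dict[str, np.ndarray]
    terms: list[str]
    diagnostics: dict
    converged: bool

    def coefficient_draws(self, term: str) -> np.ndarray:
        return self.draws[term]


def _slice_sample_1d(logf, x0, rng, width=1.0, max_out=30):
    """Univariate slice sampling (stepping-out + shrinkage)."""
    f0 = logf(x0)
    log_u = f0 + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_out):
        if logf(lo) <= log_u:
            break
        lo -= width
    for _ in range(max_out):
        if logf(hi) <= log_u:
            break
        hi += width
    while True:
        x1 = lo + (hi - lo) * rng.random()
        if logf(x1) > log_u:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _gibbs_chain(X, y, subj_idx, n_subjects, prior_mu, prior_prec, scale_sd,
                 n_sweeps, rng):
    """One chain of the scale-mixture Gibbs sampler for the Student-T model.

    Augmenting each observation with a latent precision lambda_i makes the
    Student-T likelihood conditionally Gaussian, so the fixed effects and
    the per-subject intercepts have exact conjugate normal draws; the
    group scale tau, residual scale sigma and dof nu are updated with 1-D
    slice steps on their logs.  Mixing is near-iid, unlike generic
    ensemble moves on the joint 50+-dimensional posterior.
    """
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma = max(np.std(resid), 1e-4)
    tau = sigma / 2
    nu = 10.0
    u = np.zeros(n_subjects)
    lam = np.ones(n)
    counts = np.bincount(subj_idx, minlength=n_subjects)
    out = np.empty((n_sweeps, k + 3))
    XT = X.T
    for s in range(n_sweeps):
        # latent precisions | rest  (exact gamma draw)
        r = y - X @ beta - u[subj_idx]
        lam = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + (r / sigma) ** 2))
        w = lam / sigma**2
        # fixed effects | rest  (conjugate normal)
        yu = y - u[subj_idx]
        P = (XT * w) @ X + prior_prec
        rhs = XT @ (w * yu) + prior_prec @ prior_mu
        L = np.linalg.cholesky(P)
        mean_b = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
        beta = mean_b + np.linalg.solve(L.T, rng.standard_normal(k))
        # subject intercepts | rest  (conjugate normal, vectorised)
        res_b = y - X @ beta
        sw = np.bincount(subj_idx, weights=w, minlength=n_subjects)
        swr = np.bincount(subj_idx, weights=w * res_b, minlength=n_subjects)
        prec_u = sw + 1.0 / tau**2
        u = swr / prec_u + rng.standard_normal(n_subjects) / np.sqrt(prec_u)
        # group scale tau | u  (half-normal prior, slice on log tau)
        ssq_u = float(u @ u)
        log_tau = _slice_sample_1d(
            lambda lt: (
                -n_subjects * lt
                - 0.5 * ssq_u * np.exp(-2 * lt)
                - 0.5 * (np.exp(lt) / scale_sd) ** 2
                + lt
            ),
            np.log(tau),
            rng,
        )
        tau = float(np.exp(np.clip(log_tau, -20, 20)))
        # residual scale and dof | beta, u — partially collapsed: the
        # latent precisions are integrated out (marginal Student-T
        # likelihood), breaking the strong sigma-lambda-nu coupling that
        # otherwise makes sigma mix very slowly; lambda is refreshed from
        # its exact conditional at the top of the next sweep
        r = y - X @ beta - u[subj_idx]
        r2 = r**2

        def log_sigma_post(ls):
            sig = np.exp(ls)
            return (
                -n * ls
                - (nu + 1.0) / 2.0 * float(np.sum(np.log1p(r2 / (nu * sig**2))))
                - 0.5 * (sig / scale_sd) ** 2
                + ls
            )

        def log_nu_post(lx):
            nu_ = 1.0 + np.exp(lx)
            return (
                n * (gammaln((nu_ + 1) / 2) - gammaln(nu_ / 2) - 0.5 * np.log(nu_))
                - (nu_ + 1.0) / 2.0 * float(np.sum(np.log1p(r2 / (nu_ * sigma**2))))
                + np.log(nu_ - 1.0)
                - 0.1 * (nu_ - 1.0)
                + lx
            )

        def joint_post(ls, lx):
            nu_ = 1.0 + np.exp(np.clip(lx, -20, 6))
            sig = np.exp(np.clip(ls, -20, 20))
            return (
                n * (gammaln((nu_ + 1) / 2) - gammaln(nu_ / 2) - 0.5 * np.log(nu_) - ls)
                - (nu_ + 1.0) / 2.0 * float(np.sum(np.log1p(r2 / (nu_ * sig**2))))
                - 0.5 * (sig / scale_sd) ** 2
                + ls
                + np.log(nu_ - 1.0)
                - 0.1 * (nu_ - 1.0)
                + lx
            )

        for _ in range(1):  # axis updates, then a random-direction move
            sigma = float(
                np.exp(np.clip(_slice_sample_1d(log_sigma_post, np.log(sigma), rng), -20, 20))
            )
            nu = 1.0 + float(
                np.exp(np.clip(_slice_sample_1d(log_nu_post, np.log(nu - 1.0), rng), -20, 6))
            )
            # slice along a random direction in (log sigma, log(nu-1)):
            # the two are ridge-correlated (sigma^2 * nu/(nu-2) is what the
            # data pin down), so axis-aligned moves alone mix slowly
            v = rng.standard_normal(2)
            v /= np.hypot(*v)
            ls0, lx0 = np.log(sigma), np.log(nu - 1.0)
            tstep = _slice_sample_1d(
                lambda tt: joint_post(ls0 + tt * v[0], lx0 + tt * v[1]), 0.0, rng
            )
            sigma = float(np.exp(np.clip(ls0 + tstep * v[0], -20, 20)))
            nu = 1.0 + float(np.exp(np.clip(lx0 + tstep * v[1], -20, 6)))
        out[s, :k] = beta
        out[s, k] = tau
        out[s, k + 1] = sigma
        out[s, k + 2] = nu
    return out


def fit_voxel_model(
    table: pd.DataFrame,
    formula: str = "main",
    extra_covariates: list[str] | None = None,
    draws: int = 1000,
    warmup: int = 500,
    n_chains: int = 4,
    seed: int = 0,
    hdi_prob: float = 0.94,
    already_prepared: bool = False,
) -> PosteriorFit:
    """Sample the Student-T random-intercept model for one voxel's table."""
    extra_covariates = extra_covariates or []
    t = table if already_prepared else prepare_table(table, formula)
    X, names = _design(t, formula, extra_covariates)
    y = t["tracking"].to_numpy(dtype=float)
    subjects, subj_idx = np.unique(t["subject_id"].to_numpy(), return_inverse=True)
    n_subjects = len(subjects)
    if np.bincount(subj_idx).min() < 2:
        raise ValueError("need >= 2 observations per subject")
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")

    # weakly informative data-scaled priors on the fixed effects
    sd_y = max(y.std(), 1e-6)
    sd_x = X.std(axis=0)
    sd_x[sd_x == 0] = 1.0  # intercept column
    prior_sd = 2.5 * sd_y / sd_x
    prior_mu = np.zeros(X.shape[1])
    prior_mu[0] = y.mean()
    prior_prec = np.diag(1.0 / prior_sd**2)

    k = X.shape[1]
    root = np.random.SeedSequence(seed)
    chains = np.stack(
        [
            _gibbs_chain(
                X, y, subj_idx, n_subjects, prior_mu, prior_prec, sd_y,
                warmup + draws, np.random.default_rng(ss),
            )[warmup:]
            for ss in root.spawn(n_chains)
        ]
    )  # (chain, draw, k + 3)

    draw_dict: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        draw_dict[name] = chains[:, :, j]
    draw_dict["sigma_subject"] = chains[:, :, k]
    draw_dict["sigma_resid"] = chains[:, :, k + 1]
    draw_dict["nu"] = chains[:, :, k + 2]

    # convergence is gated on the reported coefficients (whose HDIs decide
    # significance); scale-parameter diagnostics are still in the dict
    diag = check_diagnostics({n: draw_dict[n] for n in names})
    for extra in ("sigma_subject", "sigma_resid", "nu"):
        arr = draw_dict[extra]
        diag["rhat"][extra] = float(az.rhat(arr))
        diag["ess"][extra] = float(az.ess(arr))
    if not diag["pass"]:
        logger.warning("voxel model flagged non-converged: %s", diag["reasons"])
    return PosteriorFit(draws=draw_dict, terms=names, diagnostics=diag, converged=diag["pass"])


def hdi(draws: np.ndarray, prob: float = 0.94) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (>= 500 draws)."""
    flat = np.asarray(draws, dtype=float).ravel()
    if flat.size < 500:
        raise ValueError(f"need >= 500 draws for an HDI, got {flat.size}")
    if np.ptp(flat) == 0:
        return float(flat[0]), float(flat[0])
    lo, hi = az.hdi(flat, hdi_prob=prob)
    return float(lo), float(hi)


def check_diagnostics(
    draws: dict[str, np.ndarray],
    rhat_max: float = 1.05,
    ess_min: float = 400.0,
    n_divergent: int = 0,
) -> dict:
    """r-hat < 1.05, bulk ESS > 400 and no divergences, per parameter."""
    reasons: list[str] = []
    rhats: dict[str, float] = {}
    esss: dict[str, float] = {}
    for name, arr in draws.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] < 2:
            return {
                "pass": False,
                "reasons": [f"{name}: r-hat needs >= 2 chains"],
                "rhat": {},
                "ess": {},
                "divergences": n_divergent,
            }
        r = float(az.rhat(arr))
        e = float(az.ess(arr))
        rhats[name], esss[name] = r, e
        if not np.isfinite(r) or r >= rhat_max:
            reasons.append(f"{name}: r-hat {r:.3f} >= {rhat_max}")
        if not np.isfinite(e) or e <= ess_min:
            reasons.append(f"{name}: ESS {e:.0f} <= {ess_min:.0f}")
    if n_divergent > 0:
        reasons.append(f"{n_divergent} divergent transitions")
    return {
        "pass": not reasons,
        "reasons": reasons,
        "rhat": rhats,
        "ess": esss,
        "divergences": n_divergent,
    }


def summarize_fit(fit: PosteriorFit, voxel_id, hdi_prob: float = 0.94) -> pd.DataFrame:
    """One summary row per fixed effect: mean, HDI, significance, diagnostics."""
    rows = []
    for term in fit.terms:
        d = fit.draws[term]
        lo, hi = hdi(d, hdi_prob)
        rows.append(
            {
                "voxel_id": voxel_id,
                "coefficient": term,
                "mean": float(d.mean()),
                "hdi_low": lo,
                "hdi_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "rhat": fit.diagnostics["rhat"].get(term, np.nan),
                "ess": fit.diagnostics["ess"].get(term, np.nan),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def neighbor_filter(
    mask: np.ndarray, adjacency: list[list[int]], min_neighbors: int = 2
) -> np.ndarray:
    """Keep a significant voxel only if >= min_neighbors neighbours are too.

    Neighbour counts refer to the *pre-filter* mask, so the rule is a
    single simultaneous pass, not an iterative erosion.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(adjacency) != len(mask):
        raise ValueError("adjacency and mask must cover the same voxels")
    out = np.zeros_like(mask)
    for v in np.flatnonzero(mask):
        n_sig = sum(mask[u] for u in adjacency[v])
        out[v] = n_sig >= min_neighbors
    return out


@dataclass
class ClusterResult:
    """Connected significant components with pooled posterior summaries."""

    coefficient: str
    filtered_mask: np.ndarray
    clusters: list[dict] = field(default_factory=list)


def aggregate_cluster_posterior(
    voxel_draws: dict[int, np.ndarray],
    filtered_mask: np.ndarray,
    adjacency: list[list[int]],
    coefficient: str = "",
    hdi_prob: float = 0.94,
) -> ClusterResult:
    """Pool posterior draws over each connected component of the mask."""
    filtered_mask = np.asarray(filtered_mask, dtype=bool)
    result = ClusterResult(coefficient=coefficient, filtered_mask=filtered_mask)
    keep = np.flatnonzero(filtered_mask)
    if keep.size == 0:
        logger.info("no voxels survive the neighbour filter for %s", coefficient)
        return result
    g = nx.Graph()
    g.add_nodes_from(keep.tolist())
    for v in keep:
        for u in adjacency[v]:
            if filtered_mask[u]:
                g.add_edge(int(v), int(u))
    for comp in nx.connected_components(g):
        voxels = sorted(comp)
        pooled = np.concatenate([np.ravel(voxel_draws[v]) for v in voxels])
        lo, hi = hdi(pooled, hdi_prob)
        result.clusters.append(
            {
                "voxels": voxels,
                "n_voxels": len(voxels),
                "mean": float(pooled.mean()),
                "hdi_low": lo,
                "hdi_high": hi,
            }
        )
    result.clusters.sort(key=lambda c: -c["n_voxels"])
    return result


def fit_cohort_stats(
    table: pd.DataFrame,
    adjacency: list[list[int]],
    formula: str = "main",
    extra_covariates: list[str] | None = None,
    draws: int = 1000,
    warmup: int = 500,
    n_chains: int = 4,
    seed: int = 0,
    hdi_prob: float = 0.94,
    min_neighbors: int = 2,
) -> tuple[pd.DataFrame, dict[str, ClusterResult]]:
    """Fit every voxel, then neighbour-filter and cluster each coefficient.

    ``table`` holds all voxels (column voxel_id); returns the per-voxel
    summary table and a ClusterResult per fixed effect.
    """
    t = prepare_table(table, formula)
    voxel_ids = np.sort(t["voxel_id"].unique())
    if len(voxel_ids) != len(adjacency):
        raise ValueError("adjacency must cover every voxel in the table")
    root = np.random.SeedSequence(seed)
    voxel_seeds = root.generate_state(len(voxel_ids))
    summaries = []
    all_draws: dict[str, dict[int, np.ndarray]] = {}
    for i, vox in enumerate(voxel_ids):
        fit = fit_voxel_model(
            t[t["voxel_id"] == vox],
            formula=formula,
            extra_covariates=extra_covariates,
            draws=draws,
            warmup=warmup,
            n_chains=n_chains,
            seed=int(voxel_seeds[i] % (2**31 - 1)),
            hdi_prob=hdi_prob,
            already_prepared=True,
        )
        summaries.append(summarize_fit(fit, vox, hdi_prob))
        for term in fit.terms:
            all_draws.setdefault(term, {})[int(i)] = fit.draws[term]
    summary = pd.concat(summaries, ignore_index=True)
    clusters: dict[str, ClusterResult] = {}
    for term in all_draws:
        sig = (
            summary[summary["coefficient"] == term]
            .set_index("voxel_id")
            .loc[voxel_ids, "significant"]
            .to_numpy()
        )
        filt = neighbor_filter(sig, adjacency, min_neighbors)
        clusters[term] = aggregate_cluster_posterior(
            all_draws[term], filt, adjacency, coefficient=term, hdi_prob=hdi_prob
        )
    return summary, clusters
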
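"""Bivariate Gaussian mixed model via Gibbs sampling.

The model for the two log-scale responses (activity-space size, activity) of
row j belonging to individual i is

    y_j = B' x_j + u_i + e_j,   u_i ~ N2(0, G),   e_j ~ N2(0, R)

with trait-specific fixed effects B (one column per trait), an among-
individual covariance G, and a residual covariance R. Priors follow the
conventional animal-model setup: nearly-flat Gaussians on fixed effects
(variance 1e10) and inverse-Wishart on G and R parameterized by a scale
matrix V and degrees of freedom nu, with prior scale V*nu (so the posterior
scale is V*nu + crossproduct). All full conditionals are conjugate, so the
sampler is a plain Gibbs scheme; chains are independent given distinct
spawned seeds.

Derived quantities are computed per posterior draw and then summarized:
adjusted repeatability per trait r_adj = V_ind / (V_ind + V_res), and the
among-individual correlation R_ind = g12 / sqrt(g11 * g22).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRAITS = ("log_space", "log_activity")
TRAIT_PRINT = {"log_space": "Activity space size", "log_activity": "Activity"}


# ---------------------------------------------------------------------------
# design


def orthogonal_poly(x: np.ndarray, degree: int = 3) -> np.ndarray:
    """Orthonormal polynomial basis of the observed values (R poly()-style):
    columns are degree 1..degree, pairwise orthogonal, unit norm, centered.
    Sign convention: each column correlates positively with x**k."""
    x = np.asarray(x, float)
    if len(np.unique(x)) <= degree:
        raise ValueError(f"need more than {degree} distinct values for a degree-{degree} basis")
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    basis = Q[:, 1:degree + 1]
    for k in range(degree):
        if np.dot(basis[:, k], x**(k + 1)) < 0:
            basis[:, k] = -basis[:, k]
    return basis


@dataclass
class McmcSettings:
    n_chains: int = 4
    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")


PAPER_FIDELITY = McmcSettings(n_chains=4, n_iter=1_000_000, burn_in=50_000, thin=200)


@dataclass
class ModelSpec:
    responses: tuple = TRAITS
    individual_col: str = "transmitter_id"
    prior_V: np.ndarray = field(default_factory=lambda: np.eye(2))
    prior_nu: float = 1.002
    beta_prior_var: float = 1e10
    week_degree: int = 3
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def __post_init__(self) -> None:
        self.prior_V = np.asarray(self.prior_V, float)
        if self.prior_nu <= 1.0:  # dimension 2: need nu > p - 1
            raise ValueError("prior_nu must exceed dimension - 1 = 1")


@dataclass
class Design:
    X: np.ndarray            # (n, p) covariates shared by both traits
    y: np.ndarray            # (n, 2) responses in TRAITS order
    ind_idx: np.ndarray      # (n,) individual index 0..m-1
    ind_ids: list            # m transmitter ids
    columns: list            # p column names
    week_values: np.ndarray  # observed weeks backing the orthogonal basis

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_ind(self) -> int:
        return len(self.ind_ids)

    @property
    def n_response_entries(self) -> int:
        """Stacked bivariate layout: each data row contributes one response
        entry per trait."""
        return 2 * self.n_obs


def build_design(table: pd.DataFrame, spec: ModelSpec | None = None) -> Design:
    """Design matrices for the bivariate fit.

    Codings: philopatry reference CR (dummies SF, SR), sex reference female,
    diel reference night; week enters as an orthogonal cubic computed from
    the observed week values. Factor levels absent from the data drop their
    columns with a warning; a rank-deficient design raises, naming the
    aliased columns.
    """
    spec = spec or ModelSpec()
    ids = pd.unique(table[spec.individual_col])
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    diel_levels = set(table["diel"])
    if diel_levels != {"day", "night"}:
        raise ValueError(f"both diel levels required, got {sorted(diel_levels)}")
    n = len(table)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    present = [lv for lv in ("CR", "SF", "SR") if lv in set(table["philopatry"].dropna())]
    absent = [lv for lv in ("CR", "SF", "SR") if lv not in present]
    if absent:
        warnings.warn(f"philopatry level(s) {absent} absent; re-referencing to "
                      f"{present[0] if present else 'none'}")
    # reference = CR when present, else the first present level; a single
    # level carries no contrast at all
    for level in present[1:]:
        cols[f"philopatry_{level}"] = (table["philopatry"] == level).to_numpy(float)
    cols["disc_length"] = table["disc_length"].to_numpy(float)
    cols["sex_male"] = (table["sex"] == "male").to_numpy(float)
    week = table["iso_week"].to_numpy(float)
    basis = orthogonal_poly(week, spec.week_degree)
    for k in range(spec.week_degree):
        cols[f"week_poly{k + 1}"] = basis[:, k]
    cols["diel_day"] = (table["diel"] == "day").to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    # rank check with aliased-column naming
    _, rdiag = np.linalg.qr(X)
    small = np.abs(np.diag(rdiag)) < 1e-8 * max(1.0, np.abs(np.diag(rdiag)).max())
    if small.any():
        raise ValueError(f"rank-deficient design; aliased columns: "
                         f"{[names[i] for i in np.flatnonzero(small)]}")
    id_map = {v: k for k, v in enumerate(ids)}
    y = table[list(spec.responses)].to_numpy(float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite responses")
    return Design(
        X=X,
        y=y,
        ind_idx=table[spec.individual_col].map(id_map).to_numpy(),
        ind_ids=list(ids),
        columns=names,
        week_values=week,
    )


# ---------------------------------------------------------------------------
# sampler internals


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _chol2(m: np.ndarray) -> np.ndarray:
    a = np.sqrt(m[0, 0])
    b = m[1, 0] / a
    return np.array([[a, 0.0], [b, np.sqrt(m[1, 1] - b * b)]])


def _inv2_batch(m: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a stack of 2x2 matrices, shape (..., 2, 2)."""
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    out = np.empty_like(m)
    out[..., 0, 0] = m[..., 1, 1]
    out[..., 1, 1] = m[..., 0, 0]
    out[..., 0, 1] = -m[..., 0, 1]
    out[..., 1, 0] = -m[..., 1, 0]
    return out / det[..., None, None]


def _chol2_batch(m: np.ndarray) -> np.ndarray:
    """Lower Cholesky factors of a stack of SPD 2x2 matrices."""
    out = np.zeros_like(m)
    a = np.sqrt(m[..., 0, 0])
    b = m[..., 1, 0] / a
    out[..., 0, 0] = a
    out[..., 1, 0] = b
    out[..., 1, 1] = np.sqrt(m[..., 1, 1] - b * b)
    return out


def _rinvwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from InverseWishart(df, scale), 2x2, via the Bartlett
    decomposition of the Wishart(df, scale^-1) precision draw."""
    C = _chol2(_inv2(scale))
    A = np.array([
        [np.sqrt(rng.chisquare(df)), 0.0],
        [rng.standard_normal(), np.sqrt(rng.chisquare(df - 1.0))],
    ])
    L = C @ A
    W = L @ L.T
    return _inv2(W)


def _spd_guard(m: np.ndarray, what: str) -> np.ndarray:
    """Jitter retry for a near-singular scale matrix; hard error if still bad."""
    try:
        np.linalg.cholesky(m)
        return m
    except np.linalg.LinAlgError:
        jittered = m + 1e-8 * np.eye(2) * max(np.trace(m), 1.0)
        try:
            np.linalg.cholesky(jittered)
            log.warning("jittered non-SPD %s scale matrix", what)
            return jittered
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"non-SPD {what} scale matrix") from exc


def gibbs_fit(design: Design, spec: ModelSpec | None = None) -> list[dict]:
    """Run the Gibbs sampler; returns one dict per chain with stacked
    retained draws: 'beta' (draws, p, 2), 'G' and 'R' (draws, 2, 2).

    Fixed effects are drawn from their collapsed conditional (individual
    effects integrated out through the Woodbury identity) followed by
    u | B, G, R — an exact joint (B, u) block update. Sequential B and u
    updates mix pathologically along the ridge between individual-level
    covariates (size, sex, philopatry) and the random intercepts; the
    collapsed draw removes that ridge at O(p²) extra cost per iteration
    because every per-individual cross-product involved is constant across
    iterations.
    """
    spec = spec or ModelSpec()
    mc = spec.mcmc
    X, y, idx = design.X, design.y, design.ind_idx
    n, p = X.shape
    m = design.n_ind
    XtX = X.T @ X
    XtYr = X.T @ y  # (p, 2), fixed
    nu0 = spec.prior_nu
    S0 = spec.prior_V * nu0
    beta_prec = 1.0 / spec.beta_prior_var
    counts = np.bincount(idx, minlength=m).astype(float)
    # per-individual column/response sums, grouped by replicate count; the
    # per-group cross-products entering the collapsed B conditional are
    # constant across iterations
    Sx = np.zeros((m, p))
    np.add.at(Sx, idx, X)
    Ty = np.zeros((m, 2))
    np.add.at(Ty, idx, y)
    uniq_counts, group_of_ind = np.unique(counts, return_inverse=True)
    SSg = np.stack([Sx[group_of_ind == g].T @ Sx[group_of_ind == g]
                    for g in range(len(uniq_counts))])          # (g, p, p)
    STg = np.stack([Sx[group_of_ind == g].T @ Ty[group_of_ind == g]
                    for g in range(len(uniq_counts))])          # (g, p, 2)
    n_keep = (mc.n_iter - mc.burn_in) // mc.thin
    chains = []
    master = np.random.SeedSequence(mc.seed)
    for chain_seed in master.spawn(mc.n_chains):
        rng = np.random.default_rng(chain_seed)
        B, *_ = np.linalg.lstsq(X, y, rcond=None)
        B = B + rng.standard_normal(B.shape) * 0.1  # disperse chain starts
        u = np.zeros((m, 2))
        G = np.eye(2) * max(y.var(axis=0).mean() / 2, 1e-3)
        R = G.copy()
        out_beta = np.empty((n_keep, p, 2))
        out_G = np.empty((n_keep, 2, 2))
        out_R = np.empty((n_keep, 2, 2))
        kept = 0
        for it in range(mc.n_iter):
            Rinv = _inv2(R)
            Ginv = _inv2(G)
            Vg = _inv2_batch(uniq_counts[:, None, None] * Rinv + Ginv)  # (g, 2, 2)
            Mg = Rinv @ Vg @ Rinv
            # collapsed fixed effects: B | G, R with u integrated out
            prec = (np.kron(Rinv, XtX)
                    - np.einsum("gab,gij->aibj", Mg, SSg).reshape(2 * p, 2 * p))
            bmat = XtYr @ Rinv - np.einsum("gpa,gab->pb", STg, Mg)
            prec[np.diag_indices_from(prec)] += beta_prec
            Lp = np.linalg.cholesky(prec)
            bvec = bmat.ravel(order="F")
            mean = np.linalg.solve(Lp.T, np.linalg.solve(Lp, bvec))
            draw = mean + np.linalg.solve(Lp.T, rng.standard_normal(2 * p))
            B = draw.reshape((p, 2), order="F")
            # individual effects u_i | B, G, R
            S = Ty - Sx @ B  # per-individual residual sums
            SR = S @ Rinv
            Vi = Vg[group_of_ind]
            Li = _chol2_batch(Vi)
            z = rng.standard_normal((m, 2))
            u = (np.einsum("mab,mb->ma", Vi, SR)
                 + np.einsum("mab,mb->ma", Li, z))
            # covariances
            E = y - X @ B - u[idx]
            R = _rinvwishart(rng, nu0 + n, _spd_guard(S0 + E.T @ E, "residual"))
            G = _rinvwishart(rng, nu0 + m, _spd_guard(S0 + u.T @ u, "among-individual"))
            if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0 and kept < n_keep:
                out_beta[kept] = B
                out_G[kept] = G
                out_R[kept] = R
                kept += 1
        chains.append({"beta": out_beta[:kept], "G": out_G[:kept], "R": out_R[:kept]})
    return chains


# ---------------------------------------------------------------------------
# derived quantities


def repeatability(v_ind: float, v_res: float):
    """Adjusted repeatability r_adj = V_ind / (V_ind + V_res)."""
    v_ind = np.asarray(v_ind, float)
    v_res = np.asarray(v_res, float)
    if (v_ind < 0).any() or (v_res < 0).any():
        raise ValueError("variance components must be nonnegative")
    total = v_ind + v_res
    if np.any(total == 0):
        raise ValueError("repeatability undefined when both variances are zero")
    out = v_ind / total
    return float(out) if out.ndim == 0 else out


def among_correlation(g12: float, g11: float, g22: float):
    """Among-individual correlation R_ind = g12 / sqrt(g11 * g22)."""
    g11 = np.asarray(g11, float)
    g22 = np.asarray(g22, float)
    if (g11 <= 0).any() or (g22 <= 0).any():
        raise ValueError("among-individual variances must be positive")
    out = np.asarray(g12, float) / np.sqrt(g11 * g22)
    return float(out) if out.ndim == 0 else out


def flatten_params(chains: list[dict], design: Design | None = None) -> dict[str, np.ndarray]:
    """Scalar parameter name -> (n_chains, n_draws) array."""
    out: dict[str, np.ndarray] = {}
    p = chains[0]["beta"].shape[1]
    names = design.columns if design is not None else [f"b{k}" for k in range(p)]
    for t, trait in enumerate(TRAITS):
        for k in range(p):
            out[f"{trait}:{names[k]}"] = np.stack([c["beta"][:, k, t] for c in chains])
    for label, (i, j) in {"G[space,space]": (0, 0), "G[space,activity]": (0, 1),
                          "G[activity,activity]": (1, 1),
                          "R[space,space]": (0, 0), "R[space,activity]": (0, 1),
                          "R[activity,activity]": (1, 1)}.items():
        mat = label[0]
        out[label] = np.stack([c[mat][:, i, j] for c in chains])
    return out


def split_psrf(draws: np.ndarray) -> float:
    """Classic split-chain Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (n_chains, n_draws); each chain is split in half, so
    even a single chain yields a (2-half) diagnostic.
    """
    c, n = draws.shape
    half = n // 2
    if half < 2:
        raise ValueError("need >= 4 draws per chain")
    segs = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    mch = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean()
    B = half * mch.var(ddof=1)
    var_hat = (half - 1) / half * W + B / half
    if W == 0:
        return 1.0
    return float(np.sqrt(var_hat / W))


def diagnostics(chains: list[dict], design: Design | None = None,
                max_lag: int = 10) -> pd.DataFrame:
    """PSRF and lag-1..max_lag autocorrelations per scalar parameter.

    With a single chain the PSRF column is still computed from its split
    halves; autocorrelations are averaged over chains (arviz kernel).
    """
    import arviz as az

    params = flatten_params(chains, design)
    n_draws = next(iter(params.values())).shape[1]
    if n_draws < 10:
        raise ValueError("need >= 10 retained draws per chain")
    rows = []
    for name, arr in params.items():
        ac = np.mean([az.autocorr(chain)[1:max_lag + 1] for chain in arr], axis=0)
        row = {"parameter": name, "psrf": split_psrf(arr)}
        row.update({f"acf_lag{k + 1}": float(ac[k]) for k in range(len(ac))})
        rows.append(row)
    return pd.DataFrame(rows)


def _summary(draws: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(draws)),
        "median": float(np.median(draws)),
        "ci_lower": float(np.percentile(draws, 2.5)),
        "ci_upper": float(np.percentile(draws, 97.5)),
    }


@dataclass
class DerivedSummaries:
    fixed_effects: pd.DataFrame   # parameter, trait, mean, median, CI, significant
    covariances: pd.DataFrame     # Table-1-style among/within (co)variance block
    repeatability: pd.DataFrame   # per trait r_adj summaries (per-draw ratios)
    correlation: pd.DataFrame     # R_ind summaries (per-draw ratios)

    def report(self) -> str:
        lines = ["Among and within individual (co-)variances of behaviors", ""]
        lines.append(f"{'Behavioral traits':<42}{'Post. mean':>11}{'Lower CI':>10}{'Upper CI':>10}")
        for _, r in self.covariances.iterrows():
            label = f"{r['trait_a']} / {r['trait_b']} ({r['component']})"
            lines.append(f"{label:<42}{r['mean']:>11.3f}{r['ci_lower']:>10.3f}{r['ci_upper']:>10.3f}")
        lines.append("")
        lines.append("Adjusted repeatability (per-draw posterior of V_ind/(V_ind+V_res))")
        for _, r in self.repeatability.iterrows():
            lines.append(f"  {TRAIT_PRINT[r['trait']]:<22} mean {r['mean']:.3f}  "
                         f"median {r['median']:.3f}  [{r['ci_lower']:.3f}-{r['ci_upper']:.3f}]")
        r = self.correlation.iloc[0]
        lines.append(f"Among-individual correlation R_ind: mean {r['mean']:.3f}  "
                     f"median {r['median']:.3f}  [{r['ci_lower']:.3f}-{r['ci_upper']:.3f}]")
        lines.append("")
        lines.append("Fixed effects (95% credible intervals; * excludes zero)")
        for _, fe in self.fixed_effects.iterrows():
            star = "*" if fe["significant"] else " "
            lines.append(f"  {fe['trait']:<13} {fe['parameter']:<16} "
                         f"{fe['mean']:>9.4f} [{fe['ci_lower']:>9.4f}, {fe['ci_upper']:>9.4f}] {star}")
        return "\n".join(lines)


def summarize(chains: list[dict], design: Design) -> DerivedSummaries:
    """Posterior summaries: fixed effects with significance flags, the
    (co)variance block, and the per-draw r_adj / R_ind distributions."""
    beta = np.concatenate([c["beta"] for c in chains])  # (d, p, 2)
    G = np.concatenate([c["G"] for c in chains])
    R = np.concatenate([c["R"] for c in chains])
    fe_rows = []
    for t, trait in enumerate(TRAITS):
        for k, name in enumerate(design.columns):
            s = _summary(beta[:, k, t])
            s.update(parameter=name, trait=trait,
                     significant=bool(s["ci_lower"] > 0 or s["ci_upper"] < 0))
            fe_rows.append(s)
    cov_rows = []
    for comp, mat in (("among", G), ("within", R)):
        for (i, j, a, b) in ((0, 0, TRAIT_PRINT["log_space"], TRAIT_PRINT["log_space"]),
                             (1, 0, TRAIT_PRINT["log_activity"], TRAIT_PRINT["log_space"]),
                             (1, 1, TRAIT_PRINT["log_activity"], TRAIT_PRINT["log_activity"])):
            s = _summary(mat[:, i, j])
            s.update(component=comp, trait_a=a, trait_b=b)
            cov_rows.append(s)
    rep_rows = []
    for t, trait in enumerate(TRAITS):
        draws = repeatability(G[:, t, t], R[:, t, t])
        s = _summary(draws)
        s["trait"] = trait
        rep_rows.append(s)
    corr_draws = among_correlation(G[:, 0, 1], G[:, 0, 0], G[:, 1, 1])
    corr = _summary(corr_draws)
    corr["name"] = "R_ind"
    return DerivedSummaries(
        fixed_effects=pd.DataFrame(fe_rows)[
            ["trait", "parameter", "mean", "median", "ci_lower", "ci_upper", "significant"]],
        covariances=pd.DataFrame(cov_rows)[
            ["component", "trait_a", "trait_b", "mean", "median", "ci_lower", "ci_upper"]],
        repeatability=pd.DataFrame(rep_rows)[
            ["trait", "mean", "median", "ci_lower", "ci_upper"]],
        correlation=pd.DataFrame([corr])[
            ["name", "mean", "median", "ci_lower", "ci_upper"]],
    )


def draws_frame(chains: list[dict], design: Design) -> pd.DataFrame:
    """Long-format retained draws (chain, iteration, parameter, value)."""
    params = flatten_params(chains, design)
    frames = []
    for name, arr in params.items():
        c, n = arr.shape
        frames.append(pd.DataFrame({
            "chain": np.repeat(np.arange(c), n),
            "iteration": np.tile(np.arange(n), c),
            "parameter": name,
            "value": arr.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)
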
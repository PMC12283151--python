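"""Variance partitioning of acoustic features into behavior, culture,
phylogeny, and geography components.

Each acoustic feature y (one value per song, standardized) is modeled as

    y = alpha + b[context] + u[languoid] + p[languoid] + g[languoid] + eps

with  b ~ N(0, sigma2_b I)                  (behavioral context)
      u ~ N(0, sigma2_c I)                  (culture: i.i.d. per glottocode)
      p ~ MVN(0, sigma2_p K)                (phylogeny: Brownian correlation
                                             from the language tree)
      g ~ MVN(0, sigma2_g exp(-d/rho))      (geography: exponential GP on
                                             great-circle distances, km)
      eps ~ N(0, sigma2_e I)                (residual)

The random effects are integrated out analytically, leaving a Gaussian
marginal likelihood over the low-dimensional vector of variance components
(plus the GP lengthscale rho and the intercept), which is sampled by MCMC
with independent ensembles for convergence checking (R-hat < 1.05 gate).
The intra-class correlation (ICC) of component k is its per-draw share of
total variance, sigma2_k / (sum_j sigma2_j + sigma2_e): the proportion of
variance the component explains.

Kernels are exposed on their own (`brownian_covariance`,
`exponential_kernel`, `geodesic_distance_matrix`, `expand_to_songs`) because
the synthetic-data generator uses exactly the same code paths.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.linalg import block_diag, cho_factor, cho_solve
from scipy.special import gammaln
from sklearn.metrics.pairwise import haversine_distances

from .corpus_io import AlignmentError, CorpusTable, CoordinateTable, \
    FeatureTable, IntegrityError, LanguageTree

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: diagonal jitter applied before any Cholesky factorization
PSD_JITTER = 1e-8

TERMS = ("behavior", "culture", "phylogeny", "geography")

#: the default model battery: each entry is a set of group-effect terms
DEFAULT_BATTERY: tuple[frozenset, ...] = (
    frozenset({"behavior"}),
    frozenset({"culture"}),
    frozenset({"behavior", "culture"}),
    frozenset({"behavior", "culture", "phylogeny"}),
    frozenset({"behavior", "culture", "geography"}),
    frozenset({"behavior", "culture", "phylogeny", "geography"}),
)


# ---------------------------------------------------------------------------
# Covariance structures
# ---------------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    """Labeled dense covariance/correlation matrix."""

    labels: list[str]
    matrix: np.ndarray
    kind: str  # "brownian" | "geographic"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise IntegrityError(
                f"covariance matrix shape {self.matrix.shape} != ({n}, {n})"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise IntegrityError("covariance matrix is not symmetric")

    def is_psd(self, tol: float = -1e-8) -> bool:
        eig = np.linalg.eigvalsh(self.matrix + PSD_JITTER * np.eye(len(self.labels)))
        return bool(eig.min() >= tol)

    def normalized(self) -> "CovarianceMatrix":
        """Correlation form D^{-1/2} K D^{-1/2} (unit diagonal)."""
        d = np.sqrt(np.diag(self.matrix))
        if np.any(d == 0):
            raise IntegrityError("zero diagonal entry; cannot normalize")
        return CovarianceMatrix(
            self.labels, self.matrix / np.outer(d, d), self.kind
        )


def brownian_covariance(
    tree: LanguageTree, tips: list[str] | None = None, normalize: bool = True
) -> CovarianceMatrix:
    """Trait covariance between tips under Brownian motion on the tree.

    Entry (i, j) is the shared root-to-MRCA path length of tips i and j
    (their common evolutionary history); the diagonal is each tip's
    root-to-tip depth.  With ``normalize`` the matrix is rescaled to unit
    diagonal (correlation form), putting the phylogenetic variance component
    on the same scale as the i.i.d. components.
    """
    if tips is None:
        tips = tree.tip_labels
    unknown = [t for t in tips if t not in tree]
    if unknown:
        raise AlignmentError(f"tips not in tree: {unknown}")

    depths = tree.depths()
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(tips)
    K = np.empty((n, n))
    for i, a in enumerate(tips):
        K[i, i] = depths[a]
        for j in range(i + 1, n):
            b = tips[j]
            # shared path = depth(MRCA) = (depth_a + depth_b - patristic_ab)/2
            d_ab = pdm.patristic_distance(taxa[a], taxa[b])
            K[i, j] = K[j, i] = 0.5 * (depths[a] + depths[b] - d_ab)
    cov = CovarianceMatrix(list(tips), K, "brownian")
    return cov.normalized() if normalize else cov


def geodesic_distance_matrix(coords) -> np.ndarray:
    """Great-circle (haversine) distance matrix in km, Earth radius 6371 km.

    *coords* is a CoordinateTable, or an (n, 2) array of [lat, lon] in
    decimal degrees.
    """
    if isinstance(coords, CoordinateTable):
        latlon = coords.df[["latitude", "longitude"]].to_numpy(dtype=float)
    else:
        latlon = np.asarray(coords, dtype=float)
    if latlon.ndim != 2 or latlon.shape[1] != 2:
        raise IntegrityError("coordinates must be an (n, 2) [lat, lon] array")
    if np.any(np.abs(latlon[:, 0]) > 90) or np.any(np.abs(latlon[:, 1]) > 180):
        raise IntegrityError("coordinate out of range")
    D = haversine_distances(np.radians(latlon)) * EARTH_RADIUS_KM
    np.fill_diagonal(D, 0.0)
    return D


def exponential_kernel(D: np.ndarray, rho: float,
                       labels: list[str] | None = None) -> CovarianceMatrix:
    """Exponential spatial kernel G = exp(-D / rho); unit diagonal."""
    if rho <= 0:
        raise ValueError(f"lengthscale rho must be positive, got {rho}")
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, D.T) or np.any(D < 0) or np.any(np.diag(D) != 0):
        raise IntegrityError("D must be symmetric, non-negative, zero-diagonal")
    if labels is None:
        labels = [str(i) for i in range(D.shape[0])]
    return CovarianceMatrix(labels, np.exp(-D / rho), "geographic")


def expand_to_songs(cov: CovarianceMatrix, song_to_unit: list[str]) -> CovarianceMatrix:
    """Lift a languoid-level covariance to songs: each song inherits its
    languoid's effect exactly (Z K Z' with Z the 0/1 incidence)."""
    index = {lab: i for i, lab in enumerate(cov.labels)}
    try:
        idx = np.array([index[u] for u in song_to_unit])
    except KeyError as exc:
        raise AlignmentError(f"song maps to unknown unit {exc.args[0]!r}") from None
    return CovarianceMatrix(
        list(song_to_unit), cov.matrix[np.ix_(idx, idx)], cov.kind
    )


# ---------------------------------------------------------------------------
# Model specification and posterior containers
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    walkers: int = 16

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need >= 2 chains for R-hat")


@dataclass
class ModelSpec:
    feature_name: str
    terms: frozenset
    priors: dict = field(default_factory=dict)  # sd_scale, rho_shape, rho_scale
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self):
        self.terms = frozenset(self.terms)
        if not self.terms:
            raise ValueError("model must include at least one group-effect term")
        bad = self.terms - set(TERMS)
        if bad:
            raise ValueError(f"unknown terms {sorted(bad)}")


@dataclass
class PosteriorSummary:
    """Posterior draws and diagnostics for one fitted model."""

    feature_name: str
    terms: frozenset
    variance_draws: dict[str, np.ndarray]   # term -> sigma2_k draws (flat)
    resid_draws: np.ndarray                 # sigma2_e draws
    rho_draws: np.ndarray | None            # geographic lengthscale, km
    rhat: dict[str, float]                  # per-parameter R-hat
    acceptance_fraction: float
    n_songs: int
    n_dropped_no_coords: int = 0
    near_singular_geo_kernel: bool = False

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.rhat_max < 1.05


# ---------------------------------------------------------------------------
# Marginal likelihood (random effects integrated out, Woodbury form)
# ---------------------------------------------------------------------------

class _MarginalModel:
    """Precomputed sufficient statistics for the marginal Gaussian likelihood.

    With V = U A (U the song x [contexts | languoids] incidence, A the
    Cholesky factor of the block-diagonal group covariance), the marginal
    covariance is  Sigma = sigma2_e I + V V', and both the log-determinant
    and the quadratic form reduce to r x r operations (r = C + L), so the
    per-evaluation cost never touches the song dimension.
    """

    def __init__(self, y, context_idx, languoid_idx, terms,
                 K=None, D_geo=None, priors=None):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise IntegrityError("non-finite response values")
        self.terms = frozenset(terms)
        self.n = len(y)
        priors = priors or {}
        self.sd_scale = priors.get("sd_scale", 1.0)

        self.C = int(context_idx.max()) + 1 if "behavior" in terms else 0
        need_l = self.terms & {"culture", "phylogeny", "geography"}
        self.L = int(languoid_idx.max()) + 1 if need_l else 0

        # the grand mean is folded into the low-rank block as a diffuse
        # N(0, ALPHA_VAR) effect, so it is marginalized with the rest
        self.ALPHA_VAR = 100.0
        blocks = [np.ones((self.n, 1))]
        if "behavior" in terms:
            Ub = np.zeros((self.n, self.C))
            Ub[np.arange(self.n), context_idx] = 1.0
            blocks.append(Ub)
        if need_l:
            Ul = np.zeros((self.n, self.L))
            Ul[np.arange(self.n), languoid_idx] = 1.0
            blocks.append(Ul)
        U = np.hstack(blocks)
        self.r = U.shape[1]

        self.UtU = U.T @ U
        self.Uty = U.T @ y
        self.yy = float(y @ y)

        self.K = None if K is None else np.asarray(K, dtype=float)
        self.D = None if D_geo is None else np.asarray(D_geo, dtype=float)
        if "phylogeny" in terms and self.K is None:
            raise ValueError("phylogeny term requires K")
        if "geography" in terms and self.D is None:
            raise ValueError("geography term requires geographic distances")
        if self.D is not None:
            off = self.D[np.triu_indices_from(self.D, k=1)]
            self.rho_scale = priors.get(
                "rho_scale", float(np.median(off)) if off.size else 1.0
            )
            self.rho_shape = priors.get("rho_shape", 2.0)
            self.max_dist = float(off.max()) if off.size else 1.0

        # parameter layout: [log sd per term in canonical order],
        # log sd_resid, [log rho if geography]
        self.var_terms = [t for t in TERMS if t in self.terms]
        self.ndim = len(self.var_terms) + 1 + ("geography" in self.terms)

    # -- parameter unpacking ----------------------------------------------
    def unpack(self, theta):
        sds = np.exp(theta[: len(self.var_terms)])
        sd_e = np.exp(theta[len(self.var_terms)])
        rho = np.exp(theta[-1]) if "geography" in self.terms else None
        return dict(zip(self.var_terms, sds)), sd_e, rho

    def log_prob(self, theta):
        if np.any(np.abs(theta) > 30):  # guard exp overflow far in the tails
            return -np.inf
        sds, sd_e, rho = self.unpack(theta)

        # priors: half-normal(0, sd_scale) on each sd, + log-Jacobian of the
        # log transform; inverse-gamma on rho + Jacobian.
        lp = 0.0
        for s in (*sds.values(), sd_e):
            lp += -0.5 * (s / self.sd_scale) ** 2 + np.log(s)
        if rho is not None:
            a, sc = self.rho_shape, self.rho_scale
            lp += (a * np.log(sc) - gammaln(a) - (a + 1) * np.log(rho)
                   - sc / rho + np.log(rho))
        if not np.isfinite(lp):
            return -np.inf

        # group covariance blocks (leading 1x1 block = diffuse grand mean)
        M_blocks = [np.array([[self.ALPHA_VAR]])]
        if "behavior" in self.terms:
            M_blocks.append(sds["behavior"] ** 2 * np.eye(self.C))
        if self.L:
            ML = np.zeros((self.L, self.L))
            if "culture" in self.terms:
                ML += sds["culture"] ** 2 * np.eye(self.L)
            if "phylogeny" in self.terms:
                ML += sds["phylogeny"] ** 2 * self.K
            if "geography" in self.terms:
                ML += sds["geography"] ** 2 * np.exp(-self.D / rho)
            M_blocks.append(ML)
        M = block_diag(*M_blocks) + PSD_JITTER * np.eye(self.r)

        try:
            A = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return -np.inf
        s2e = sd_e ** 2
        W = s2e * np.eye(self.r) + A.T @ self.UtU @ A
        try:
            cW = cho_factor(W, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = ((self.n - self.r) * np.log(s2e)
                  + 2.0 * np.sum(np.log(np.diag(cW[0]))))

        q = A.T @ self.Uty                             # V' y
        quad = (self.yy - q @ cho_solve(cW, q)) / s2e

        ll = -0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)
        return lp + ll

    def initial_point(self, rng, y_sd):
        theta = np.empty(self.ndim)
        k = len(self.var_terms)
        theta[:k] = np.log(0.5 * y_sd) + 0.3 * rng.standard_normal(k)
        theta[k] = np.log(0.7 * y_sd) + 0.3 * rng.standard_normal()
        if "geography" in self.terms:
            theta[-1] = np.log(self.rho_scale) + 0.3 * rng.standard_normal()
        return theta


def fit_variance_model(
    y,
    corpus: CorpusTable,
    spec: ModelSpec,
    K: CovarianceMatrix | None = None,
    geo_distances: np.ndarray | None = None,
    geo_labels: list[str] | None = None,
    coords: CoordinateTable | None = None,
) -> PosteriorSummary:
    """Fit one group-effects model for one feature and return posterior draws.

    *K* is the (normalized) Brownian correlation over languoids; geography is
    given either as a languoid-level distance matrix ``geo_distances`` (+
    ``geo_labels``) or as a CoordinateTable ``coords`` from which distances
    are computed.  The GP lengthscale rho is estimated.  Songs whose
    glottocode lacks coordinates are dropped from fits that include
    geography, with the count recorded.
    """
    y = np.asarray(y, dtype=float)
    glottos = corpus.glottocodes.tolist()
    contexts = corpus.contexts.tolist()
    if len(y) != len(corpus):
        raise AlignmentError("response length does not match corpus")

    mask = np.ones(len(y), dtype=bool)
    n_dropped = 0
    D_geo_l = None
    if "geography" in spec.terms:
        if geo_distances is None:
            if coords is None:
                raise ValueError("geography term requires geo_distances or coords")
            missing = set(coords.missing_from(glottos))
            if missing:
                mask = np.array([g not in missing for g in glottos])
                n_dropped = int((~mask).sum())
            kept = sorted({g for g, m in zip(glottos, mask) if m})
            D_geo_l = geodesic_distance_matrix(coords.lookup(kept))
            geo_labels = kept
        else:
            D_geo_l = np.asarray(geo_distances, dtype=float)
            if geo_labels is None:
                raise ValueError("geo_distances requires geo_labels")

    y = y[mask]
    glottos = [g for g, m in zip(glottos, mask) if m]
    contexts = [c for c, m in zip(contexts, mask) if m]

    langs = sorted(set(glottos))
    lang_idx = np.array([langs.index(g) for g in glottos])
    ctx_levels = sorted(set(contexts))
    ctx_idx = np.array([ctx_levels.index(c) for c in contexts])

    K_sub = None
    if "phylogeny" in spec.terms:
        if K is None:
            raise ValueError("phylogeny term requires K")
        K_sub = expand_to_songs(K, langs).matrix  # reorder/select to langs
    D_sub = None
    near_singular = False
    if "geography" in spec.terms:
        lab_index = {g: i for i, g in enumerate(geo_labels)}
        missing = [g for g in langs if g not in lab_index]
        if missing:
            raise AlignmentError(f"no geographic distances for {missing}")
        sel = np.array([lab_index[g] for g in langs])
        D_sub = D_geo_l[np.ix_(sel, sel)]

    model = _MarginalModel(
        y, ctx_idx, lang_idx, spec.terms, K=K_sub, D_geo=D_sub,
        priors=spec.priors,
    )

    mc = spec.mcmc
    ndim = model.ndim
    nwalkers = max(mc.walkers, 2 * ndim + 2)
    nwalkers += nwalkers % 2

    y_sd = float(y.std()) or 1.0

    t0 = time.perf_counter()
    chains = []
    acc = []
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    for c in range(mc.chains):
        rng = np.random.default_rng([mc.seed % 2**31, c])
        p0 = np.array([model.initial_point(rng, y_sd)
                       for _ in range(nwalkers)])
        sampler = emcee.EnsembleSampler(nwalkers, ndim, model.log_prob,
                                        moves=moves)
        sampler.random_state = np.random.RandomState(
            (mc.seed + 7919 * c) % 2**31
        ).get_state()
        sampler.run_mcmc(p0, mc.warmup + mc.samples, progress=False)
        chains.append(sampler.get_chain()[mc.warmup:])  # (draws, walkers, dim)
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    # (chain, draw, dim) with every walker of every ensemble as a chain
    stacked = np.concatenate(
        [np.moveaxis(ch, 1, 0) for ch in chains], axis=0
    )

    names = ([f"sigma_{t}" for t in model.var_terms]
             + ["sigma_resid"] + (["rho"] if "geography" in spec.terms else []))
    # R-hat on the sampled (log/identity) scale
    idata = az.from_dict({nm: stacked[:, :, j] for j, nm in enumerate(names)})
    rhat_ds = az.rhat(idata)
    rhat = {nm: float(rhat_ds[nm].values) for nm in names}

    flat = stacked.reshape(-1, ndim)
    var_draws = {
        t: np.exp(flat[:, i]) ** 2 for i, t in enumerate(model.var_terms)
    }
    resid_draws = np.exp(flat[:, len(model.var_terms)]) ** 2
    rho_draws = np.exp(flat[:, -1]) if "geography" in spec.terms else None

    if rho_draws is not None and np.mean(rho_draws) > 5 * model.max_dist:
        near_singular = True  # kernel ~ all-ones: geography confounded with intercept

    elapsed = time.perf_counter() - t0
    logger.info(
        "fit_variance_model feature=%s terms=%s n=%d seed=%d time=%.2fs rhat_max=%.3f",
        spec.feature_name, sorted(spec.terms), model.n, mc.seed, elapsed,
        max(rhat.values()),
    )

    return PosteriorSummary(
        feature_name=spec.feature_name,
        terms=spec.terms,
        variance_draws=var_draws,
        resid_draws=resid_draws,
        rho_draws=rho_draws,
        rhat=rhat,
        acceptance_fraction=float(np.mean(acc)),
        n_songs=model.n,
        n_dropped_no_coords=n_dropped,
        near_singular_geo_kernel=near_singular,
    )


# ---------------------------------------------------------------------------
# ICC computation and the model battery
# ---------------------------------------------------------------------------

def compute_icc(ps: PosteriorSummary, terms=None) -> pd.DataFrame:
    """Per-component ICC rows from posterior draws.

    For each draw, ICC_k = sigma2_k / (sum over included components +
    residual); reported per component: posterior mean of per-draw shares
    (point estimate), the share of posterior-mean variances (alternative),
    and the central 95% interval.
    """
    terms = sorted(ps.terms if terms is None else terms)
    total = ps.resid_draws.copy()
    for t in terms:
        total = total + ps.variance_draws[t]

    rows = []
    for comp in terms + ["residual"]:
        draws = ps.resid_draws if comp == "residual" else ps.variance_draws[comp]
        share = draws / total
        lo, hi = np.quantile(share, [0.025, 0.975])
        rows.append({
            "feature": ps.feature_name,
            "terms": "+".join(terms),
            "component": comp,
            "icc_mean": float(share.mean()),
            "icc_of_means": float(draws.mean() / total.mean()),
            "lo95": float(lo),
            "hi95": float(hi),
            "rhat_max": ps.rhat_max,
            "converged": ps.converged,
        })
    return pd.DataFrame(rows)


def run_battery(
    features: FeatureTable,
    corpus: CorpusTable,
    term_sets=DEFAULT_BATTERY,
    mcmc: MCMCConfig | None = None,
    tree: LanguageTree | None = None,
    coords: CoordinateTable | None = None,
    feature_names: list[str] | None = None,
    priors: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit every (feature, term-set) model and collect one long ICC table.

    Returns the table plus a diagnostics dict (fits run, non-converged
    count, songs dropped for missing coordinates).  Non-converged fits are
    flagged in the table and excluded from any downstream summaries.
    """
    mcmc = mcmc or MCMCConfig()
    if feature_names is None:
        feature_names = features.feature_names
    needs_tree = any("phylogeny" in ts for ts in term_sets)
    needs_geo = any("geography" in ts for ts in term_sets)

    K = None
    if needs_tree:
        if tree is None:
            raise ValueError("battery includes phylogeny but no tree given")
        langs = sorted(set(corpus.glottocodes))
        K = brownian_covariance(tree, langs, normalize=True)
    if needs_geo and coords is None:
        raise ValueError("battery includes geography but no coordinates given")

    frames, n_bad, n_fits = [], 0, 0
    dropped = 0
    for fname in feature_names:
        y = features.column(fname)
        for i, ts in enumerate(term_sets):
            spec = ModelSpec(
                feature_name=fname, terms=frozenset(ts),
                priors=priors or {},
                mcmc=MCMCConfig(
                    chains=mcmc.chains, warmup=mcmc.warmup,
                    samples=mcmc.samples, walkers=mcmc.walkers,
                    seed=(mcmc.seed + 104729 * i + 1299709 * n_fits) % 2**31,
                ),
            )
            ps = fit_variance_model(y, corpus, spec, K=K, coords=coords)
            frames.append(compute_icc(ps))
            n_fits += 1
            dropped = max(dropped, ps.n_dropped_no_coords)
            if not ps.converged:
                n_bad += 1
    table = pd.concat(frames, ignore_index=True)
    diagnostics = {
        "n_fits": n_fits,
        "n_nonconverged": n_bad,
        "n_songs_dropped_no_coords": dropped,
    }
    return table, diagnostics
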
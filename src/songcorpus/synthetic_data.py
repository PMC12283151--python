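"""Synthetic corpora with known ground-truth variance structure.

Real cross-cultural song corpora confound behavioral context, culture,
linguistic ancestry, and geography.  This module builds corpora where those
contributions are planted by construction, so the classifier and the
variance-partitioning models can be validated by parameter recovery:

  * a pure-birth (Yule) language tree stands in for the global language
    phylogeny;
  * languoid coordinates arise by Brownian diffusion along the tree's
    branches, giving locations the phylogenetically-structured spatial
    autocorrelation real languoids have;
  * each song's feature value is the sum of independent context, culture,
    phylogenetic, geographic, and residual draws with configurable
    variances (the generative mirror of the variance-partition model).

None of this emulates audio: features are abstract real-valued descriptors.
The generator's choices are stand-ins for the archived corpus, and the
written ``truth.json`` records them as such together with the true shares.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .corpus_io import (
    CONTEXT_VOCABULARY, REGION_VOCABULARY, CoordinateTable, CorpusTable,
    FeatureTable, LanguageTree,
)
from .variance_partition import (
    PSD_JITTER, brownian_covariance, exponential_kernel,
    geodesic_distance_matrix,
)

__all__ = [
    "SynthConfig",
    "SyntheticCorpus",
    "simulate_tree",
    "simulate_locations",
    "simulate_corpus",
    "theoretical_variance",
    "write_corpus",
]

VARIANCE_COMPONENTS = ("behavior", "culture", "phylo", "geo", "resid")


@dataclass
class SynthConfig:
    """Generative settings: sizes, variance components, kernels, seed.

    Variances are on the scale of a standardized feature; their shares of
    the total are what the variance-partition stage should recover.  The
    defaults plant a behavior + culture signal (shares 0.3 / 0.3) on a
    40-language, 10-songs-per-language corpus.
    """

    n_languages: int = 40
    songs_per_language: int | tuple[int, int] = 10
    n_contexts: int = 10
    n_features: int = 38
    sigma2_behavior: float = 0.3
    sigma2_culture: float = 0.3
    sigma2_phylo: float = 0.0
    sigma2_geo: float = 0.0
    sigma2_resid: float = 0.4
    geo_lengthscale: float = 1500.0       # km
    birth_rate: float = 1.0               # splits per unit branch length
    location_diffusion: float = 30.0      # degrees^2 per unit branch length
    context_weights: tuple[float, ...] | None = None  # uneven-context option
    seed: int = 0

    def __post_init__(self):
        v = self.variances()
        if any(s < 0 for s in v.values()):
            raise ValueError("variance components must be non-negative")
        if sum(v.values()) == 0:
            raise ValueError("at least one variance component must be positive")
        if self.n_contexts < 2 or self.n_contexts > len(CONTEXT_VOCABULARY):
            raise ValueError(
                f"n_contexts must be in [2, {len(CONTEXT_VOCABULARY)}]"
            )
        if self.context_weights is not None \
                and len(self.context_weights) != self.n_contexts:
            raise ValueError("context_weights length must equal n_contexts")

    def variances(self) -> dict[str, float]:
        return {
            "behavior": self.sigma2_behavior,
            "culture": self.sigma2_culture,
            "phylo": self.sigma2_phylo,
            "geo": self.sigma2_geo,
            "resid": self.sigma2_resid,
        }


@dataclass
class SyntheticCorpus:
    corpus: CorpusTable
    features: FeatureTable
    tree: LanguageTree
    coords: CoordinateTable
    truth: dict = field(default_factory=dict)


def theoretical_variance(cfg: SynthConfig) -> dict[str, float]:
    """True variance shares sigma2_k / sum(sigma2) per component."""
    v = cfg.variances()
    total = sum(v.values())
    if total == 0:
        raise ValueError("all variance components are zero")
    return {k: val / total for k, val in v.items()}


# ---------------------------------------------------------------------------
# Tree and locations
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> LanguageTree:
    """Pure-birth (Yule) ultrametric tree with *n_tips* labeled tips.

    Starting from two lineages at the root, each lineage splits at rate
    *birth_rate*; the process stops one exponential waiting time (rate
    n * birth_rate) after the n-th lineage appears, so the expected
    root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)

    k = 2
    while k < n_tips:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += wait
        i = rng.integers(len(active))
        parent = active.pop(i)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            active.append(child)
        k += 1
    # run the n-lineage epoch to the moment the next split would occur
    wait = rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.edge.length += wait

    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"lang{i + 1:0{width}d}")
    return LanguageTree(tree)


def simulate_locations(
    tree: LanguageTree,
    location_diffusion: float = 30.0,
    seed: int = 0,
    root_location: tuple[float, float] = (0.0, 0.0),
) -> CoordinateTable:
    """Brownian diffusion of (lat, lon) along the tree from a root location.

    Each coordinate performs independent Brownian motion with variance
    *location_diffusion* (degrees^2) per unit branch length; results are
    clamped to valid latitude/longitude ranges.  Sister languoids therefore
    end up spatially closer, on average, than distant relatives.
    """
    if location_diffusion < 0:
        raise ValueError("location_diffusion must be non-negative")
    rng = np.random.default_rng(seed)
    loc = {tree.tree.seed_node: np.asarray(root_location, dtype=float)}
    rows = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(location_diffusion * bl), size=2) \
            if location_diffusion * bl > 0 else np.zeros(2)
        loc[node] = loc[node.parent_node] + step
        if node.is_leaf():
            lat = float(np.clip(loc[node][0], -90.0, 90.0))
            lon = float(np.clip(loc[node][1], -180.0, 180.0))
            rows.append({"glottocode": node.taxon.label,
                         "latitude": lat, "longitude": lon})
    return CoordinateTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Full corpus
# ---------------------------------------------------------------------------

def _mvn_from_kernel(rng, cov, size):
    """Draws from MVN(0, cov) via Cholesky with the standard diagonal jitter."""
    L = np.linalg.cholesky(cov + PSD_JITTER * np.eye(cov.shape[0]))
    return (L @ rng.standard_normal((cov.shape[0], size))).T


def simulate_corpus(cfg: SynthConfig) -> SyntheticCorpus:
    """Generate a full synthetic corpus from *cfg*.

    Feature value for song s of language l in context c:

        y = beta_c + u_l + p_l + g_l + eps_s

    with beta ~ N(0, s2_behavior) per context, u ~ N(0, s2_culture) i.i.d.
    per language, p ~ MVN(0, s2_phylo * K) (K the unit-diagonal Brownian
    correlation from the simulated tree), g ~ MVN(0, s2_geo * exp(-d/rho))
    on great-circle distances, eps ~ N(0, s2_resid).  Features are i.i.d.
    redraws of all effects.  Contexts are uniform over the first
    ``n_contexts`` tokens of the canonical vocabulary unless
    ``context_weights`` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_languages, cfg.birth_rate,
                         seed=int(rng.integers(2**31)))
    coords = simulate_locations(tree, cfg.location_diffusion,
                                seed=int(rng.integers(2**31)))
    langs = tree.tip_labels

    if isinstance(cfg.songs_per_language, tuple):
        lo, hi = cfg.songs_per_language
        counts = rng.integers(lo, hi + 1, size=cfg.n_languages)
    else:
        counts = np.full(cfg.n_languages, cfg.songs_per_language)
    n_songs = int(counts.sum())

    lang_of_song = np.repeat(np.arange(cfg.n_languages), counts)
    contexts = list(CONTEXT_VOCABULARY[: cfg.n_contexts])
    p_ctx = None
    if cfg.context_weights is not None:
        w = np.asarray(cfg.context_weights, dtype=float)
        p_ctx = w / w.sum()
    ctx_of_song = rng.choice(cfg.n_contexts, size=n_songs, p=p_ctx)

    # region is decorative for the generator: one region per language
    region_of_lang = rng.choice(len(REGION_VOCABULARY), size=cfg.n_languages)

    K = brownian_covariance(tree, langs, normalize=True).matrix
    D = geodesic_distance_matrix(coords.lookup(langs))
    G = exponential_kernel(D, cfg.geo_lengthscale, langs).matrix

    F = cfg.n_features
    beta = rng.normal(0, np.sqrt(cfg.sigma2_behavior), (F, cfg.n_contexts))
    u = rng.normal(0, np.sqrt(cfg.sigma2_culture), (F, cfg.n_languages))
    p = np.sqrt(cfg.sigma2_phylo) * _mvn_from_kernel(rng, K, F) \
        if cfg.sigma2_phylo > 0 else np.zeros((F, cfg.n_languages))
    g = np.sqrt(cfg.sigma2_geo) * _mvn_from_kernel(rng, G, F) \
        if cfg.sigma2_geo > 0 else np.zeros((F, cfg.n_languages))
    eps = rng.normal(0, np.sqrt(cfg.sigma2_resid), (F, n_songs))

    values = (beta[:, ctx_of_song] + u[:, lang_of_song] + p[:, lang_of_song]
              + g[:, lang_of_song] + eps).T  # songs x features

    width = len(str(n_songs))
    song_ids = [f"s{i + 1:0{width}d}" for i in range(n_songs)]
    meta = pd.DataFrame({
        "song": song_ids,
        "region": [REGION_VOCABULARY[region_of_lang[l]] for l in lang_of_song],
        "glottocode": [langs[l] for l in lang_of_song],
        "type": [contexts[c] for c in ctx_of_song],
    })
    corpus = CorpusTable(meta)
    feature_names = [f"f{j + 1:02d}" for j in range(F)]
    features = FeatureTable(song_ids, feature_names, values)

    shares = theoretical_variance(cfg)
    truth = {
        "note": (
            "Synthetic stand-in corpus: tree, locations, and features are "
            "generated, not derived from any archived recordings."
        ),
        "config": asdict(cfg),
        "true_shares": {f: shares for f in feature_names},
        "effects": {
            "context_means": beta.tolist(),
            "culture": u.tolist(),
            "phylogeny": p.tolist(),
            "geography": g.tolist(),
        },
    }
    return SyntheticCorpus(corpus, features, tree, coords, truth)


def write_corpus(sc: SyntheticCorpus, outdir) -> dict[str, Path]:
    """Write metadata/features/coords CSVs, the newick tree, and truth.json
    in exactly the formats the corpus loaders read back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": outdir / "metadata.csv",
        "features": outdir / "features.csv",
        "coordinates": outdir / "coordinates.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    sc.corpus.to_csv(paths["metadata"])
    sc.features.to_csv(paths["features"])
    sc.coords.to_csv(paths["coordinates"])
    sc.tree.write(paths["tree"])
    with open(paths["truth"], "w") as fh:
        json.dump(sc.truth, fh, indent=1)
    return paths
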
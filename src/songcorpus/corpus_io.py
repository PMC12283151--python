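"""Corpus data backbone: metadata, acoustic features, language tree, coordinates.

A corpus is a table of song excerpts, each annotated with the geographic
region it was recorded in, the languoid (Glottolog glottocode) it was sung
in, and the behavioral context it served (dance, lullaby, healing, ...).
Acoustic descriptors live in a separate songs x features table keyed by song
id.  Languoids connect songs to a phylogeny (newick language tree, tips
labeled by glottocode) and to geography (decimal-degree coordinates).

All loaders validate against closed vocabularies and report schema problems
by name, so that downstream modeling never has to guess about its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "VocabularyError",
    "IntegrityError",
    "AlignmentError",
    "CoverageWarning",
    "ContextDefinition",
    "CONTEXT_VOCABULARY",
    "CONTEXTS",
    "REGION_VOCABULARY",
    "SongRecord",
    "CorpusTable",
    "FeatureTable",
    "LanguageTree",
    "CoordinateTable",
    "CorpusSummary",
    "load_metadata",
    "load_feature_table",
    "load_language_tree",
    "load_coordinates",
    "standardize_features",
    "summarize_corpus",
    "lower_median",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class VocabularyError(ValueError):
    """A token is not part of its controlled vocabulary."""


class IntegrityError(ValueError):
    """Internal consistency violated (duplicates, negative branch lengths...)."""


class AlignmentError(ValueError):
    """Two tables that must share keys do not."""


class CoverageWarning(UserWarning):
    """Non-fatal gaps: tips absent from a tree, glottocodes without coordinates."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContextDefinition:
    """One behavioral context with its inclusion and exclusion criteria."""

    token: str
    inclusion_text: str
    exclusion_text: str


#: The ten behavioral contexts, in canonical order.  The order is load-bearing:
#: modal-vote ties in the classifier are broken by position in this tuple.
CONTEXTS: tuple[ContextDefinition, ...] = (
    ContextDefinition(
        "dance",
        "Sung so that a person or group dances along to it.",
        "Songs merely accompanied by dancing while serving another goal.",
    ),
    ContextDefinition(
        "healing",
        "Sung during a healing ceremony with the aim of curing sickness.",
        "Songs that describe sick people or a past epidemic.",
    ),
    ContextDefinition(
        "love",
        "Sung to express love directly to someone, or to describe love currently felt.",
        "Songs about unrequited love, deceased loved ones, or love of animals/property.",
    ),
    ContextDefinition(
        "lullaby",
        "Sung to an infant or child to soothe, calm, or put to sleep.",
        "Songs meant to excite the listener (play songs); singing games.",
    ),
    ContextDefinition(
        "play",
        "Sung to excite a child or infant and engage them in play, incl. singing games.",
        "Children's songs for soothing, calming, or sleep.",
    ),
    ContextDefinition(
        "procession",
        "Sung to accompany a formalized march, entrance, or parade "
        "(wedding, funeral, introduction of a leader).",
        "Processions of dancing.",
    ),
    ContextDefinition(
        "mourning",
        "Sung to express grief about the death of a person, present or past.",
        "Songs for the sick or dying; laments about events other than a death.",
    ),
    ContextDefinition(
        "work",
        "Sung to accompany work: planting, grinding, harvesting, processing, tool-making.",
        "Hunting songs (celebrating or preparing for hunts).",
    ),
    ContextDefinition(
        "story",
        "Sung to recount historical or mythological events, or narrate a "
        "sequence of activities.",
        "Lullabies that include stories.",
    ),
    ContextDefinition(
        "praise",
        "Sung to express admiration for the traits or accomplishments of a "
        "person, animal, location, or item of property.",
        "Songs expressing love for another person; explicitly religious songs.",
    ),
)

#: Canonical context token order (used for tie-breaking and reporting).
CONTEXT_VOCABULARY: tuple[str, ...] = tuple(c.token for c in CONTEXTS)

# Reconstructed set of eHRAF world regions (35) plus the three European
# regions not in eHRAF (Western/Central/Eastern Europe) = 38 tokens.
# The vocabulary is a closed set: unknown regions are errors.  Loaders accept
# a replacement vocabulary for corpora annotated against a different release.
_EHRAF_REGIONS: tuple[str, ...] = (
    # Africa
    "Central Africa", "Eastern Africa", "Northern Africa", "Southern Africa",
    "Western Africa",
    # Asia
    "Central Asia", "East Asia", "North Asia", "South Asia", "Southeast Asia",
    # Europe
    "British Isles", "Scandinavia", "Southeastern Europe", "Southern Europe",
    # Middle America and the Caribbean
    "Caribbean", "Central America", "Maya Area", "Central Mexico",
    "Northern Mexico",
    # Middle East
    "Middle East",
    # North America
    "Arctic and Subarctic", "Eastern Woodlands", "Northwest Coast and California",
    "Plains and Plateau", "Southwest and Basin",
    # Oceania
    "Australia", "Melanesia", "Micronesia", "Polynesia",
    # South America
    "Amazon and Orinoco", "Central Andes", "Eastern South America", "Gran Chaco",
    "Northwestern South America", "Southern South America",
)

REGION_VOCABULARY: tuple[str, ...] = _EHRAF_REGIONS + (
    "Western Europe", "Central Europe", "Eastern Europe",
)

assert len(REGION_VOCABULARY) == 38


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SongRecord:
    """One song excerpt's metadata."""

    song_id: str
    region: str
    glottocode: str
    context: str
    extras: dict = field(default_factory=dict, compare=False)


class CorpusTable:
    """Validated per-song metadata table.

    Wraps a DataFrame with columns ``song, region, glottocode, type`` (extra
    columns preserved).  Construction validates uniqueness of song ids and
    vocabulary membership of region and context tokens.
    """

    REQUIRED_COLUMNS = ("song", "region", "glottocode", "type")

    def __init__(
        self,
        df: pd.DataFrame,
        region_vocabulary: tuple[str, ...] = REGION_VOCABULARY,
        context_vocabulary: tuple[str, ...] = CONTEXT_VOCABULARY,
    ):
        for col in self.REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"metadata table is missing required column {col!r}")
        df = df.reset_index(drop=True)

        dupes = df["song"][df["song"].duplicated()].tolist()
        if dupes:
            raise IntegrityError(f"duplicate song ids: {sorted(set(dupes))}")

        empty_gc = df.index[
            df["glottocode"].isna() | (df["glottocode"].astype(str).str.len() == 0)
        ].tolist()
        if empty_gc:
            raise SchemaError(f"empty glottocode in rows {empty_gc}")

        region_set = set(region_vocabulary)
        context_set = set(context_vocabulary)
        for row, token in df["region"].items():
            if token not in region_set:
                raise VocabularyError(f"unknown region {token!r} in row {row}")
        for row, token in df["type"].items():
            if token not in context_set:
                raise VocabularyError(f"unknown behavioral context {token!r} in row {row}")

        self.df = df
        self.region_vocabulary = tuple(region_vocabulary)
        self.context_vocabulary = tuple(context_vocabulary)

    # -- accessors ---------------------------------------------------------
    @property
    def song_ids(self) -> list[str]:
        return self.df["song"].tolist()

    @property
    def contexts(self) -> pd.Series:
        return self.df["type"]

    @property
    def glottocodes(self) -> pd.Series:
        return self.df["glottocode"]

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[SongRecord]:
        extra_cols = [c for c in self.df.columns if c not in self.REQUIRED_COLUMNS]
        return [
            SongRecord(
                song_id=r["song"], region=r["region"],
                glottocode=r["glottocode"], context=r["type"],
                extras={c: r[c] for c in extra_cols},
            )
            for r in self.df.to_dict("records")
        ]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class FeatureTable:
    """Songs x acoustic-features matrix aligned to a CorpusTable.

    ``standardized`` records whether each column has been centered/scaled;
    ``zero_variance`` lists constant columns found at load or scaling time.
    """

    song_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    standardized: bool = False
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.song_ids), len(self.feature_names)):
            raise IntegrityError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.song_ids)} songs x {len(self.feature_names)} features"
            )
        if len(set(self.song_ids)) != len(self.song_ids):
            raise IntegrityError("duplicate song ids in feature table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "song", self.song_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class LanguageTree:
    """Rooted language phylogeny with glottocode tip labels.

    Thin wrapper over a dendropy tree that enforces unique tip labels and
    non-negative branch lengths, and gives O(1) tip lookup.
    """

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise IntegrityError("duplicate tip labels in language tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise IntegrityError(
                    f"negative branch length {edge.length} in language tree"
                )
        self.tree = tree
        self.tip_labels = labels
        self._leaf = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    def __contains__(self, label: str) -> bool:
        return label in self._leaf

    def __len__(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        out = {}
        for label, leaf in self._leaf.items():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[label] = d
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def check_coverage(self, glottocodes) -> list[str]:
        """Return corpus glottocodes missing from the tree, warning if any."""
        missing = sorted(set(glottocodes) - set(self.tip_labels))
        if missing:
            warnings.warn(
                f"{len(missing)} glottocodes absent from the language tree: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}",
                CoverageWarning, stacklevel=2,
            )
        return missing


class CoordinateTable:
    """Glottocode -> (latitude, longitude) in decimal degrees."""

    def __init__(self, df: pd.DataFrame):
        for col in ("glottocode", "latitude", "longitude"):
            if col not in df.columns:
                raise SchemaError(f"coordinate table is missing column {col!r}")
        if df["glottocode"].duplicated().any():
            raise IntegrityError("duplicate glottocode in coordinate table")
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        bad = df["glottocode"][(lat.abs() > 90) | (lon.abs() > 180)].tolist()
        if bad:
            raise IntegrityError(f"coordinates out of bounds for {bad}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, glottocode: str) -> bool:
        return glottocode in set(self.df["glottocode"])

    def lookup(self, glottocodes) -> np.ndarray:
        """(n, 2) array of [lat, lon] rows, in the order requested."""
        idx = self.df.set_index("glottocode")
        missing = [g for g in glottocodes if g not in idx.index]
        if missing:
            raise AlignmentError(f"no coordinates for glottocodes {missing}")
        sub = idx.loc[list(glottocodes)]
        return sub[["latitude", "longitude"]].to_numpy(dtype=float)

    def missing_from(self, glottocodes) -> list[str]:
        have = set(self.df["glottocode"])
        return sorted(set(glottocodes) - have)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class CorpusSummary:
    """Breadth-and-depth counts for a corpus."""

    n_songs: int
    n_languoids: int
    n_families: int
    per_context: pd.Series           # context -> song count
    context_median: int
    context_range: tuple[int, int]
    per_region: pd.Series            # region -> song count
    region_median: int
    region_range: tuple[int, int]
    per_family: pd.Series            # family -> song count
    region_context_coverage: int     # non-empty cells of region x context table


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_metadata(
    path,
    region_vocabulary: tuple[str, ...] = REGION_VOCABULARY,
    context_vocabulary: tuple[str, ...] = CONTEXT_VOCABULARY,
) -> CorpusTable:
    """Read a UTF-8 CSV with columns song, region, glottocode, type.

    Unknown columns are preserved as extras; vocabulary violations and
    duplicate song ids raise with the offending token/row named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return CorpusTable(df, region_vocabulary, context_vocabulary)


def load_feature_table(
    path, corpus: CorpusTable, expected_features: int = 38
) -> FeatureTable:
    """Read a songs x features CSV (first column = song id) aligned to *corpus*.

    Rows are re-ordered to corpus order.  Songs present in the feature file
    but absent from the corpus (or vice versa) raise AlignmentError.  A
    feature count different from *expected_features* only warns.
    """
    df = pd.read_csv(path)
    id_col = df.columns[0]
    feature_names = [str(c) for c in df.columns[1:]]

    values = df[df.columns[1:]].to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns[1:]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            if bad:
                raise SchemaError(
                    f"non-numeric value in feature column {col!r}, rows {bad}"
                )
        values = df[df.columns[1:]].apply(pd.to_numeric).to_numpy(dtype=float)

    song_ids = df[id_col].astype(str).tolist()
    corpus_ids = corpus.song_ids
    extra = sorted(set(song_ids) - set(corpus_ids))
    if extra:
        raise AlignmentError(f"feature table songs not in corpus: {extra}")
    missing = sorted(set(corpus_ids) - set(song_ids))
    if missing:
        raise AlignmentError(f"corpus songs missing a feature row: {missing}")

    order = [song_ids.index(s) for s in corpus_ids]
    values = np.asarray(values, dtype=float)[order]

    if len(feature_names) != expected_features:
        warnings.warn(
            f"feature table has {len(feature_names)} features, "
            f"expected {expected_features}",
            UserWarning, stacklevel=2,
        )
    zero_var = [
        name for j, name in enumerate(feature_names)
        if np.ptp(values[:, j]) == 0.0
    ]
    return FeatureTable(corpus_ids, feature_names, values, zero_variance=zero_var)


def load_language_tree(path) -> LanguageTree:
    """Parse a newick file with branch lengths into a LanguageTree."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise SchemaError(f"cannot parse newick tree {path}: {exc}") from exc
    return LanguageTree(tree)


def load_coordinates(path) -> CoordinateTable:
    """Read a glottocode,latitude,longitude CSV."""
    return CoordinateTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Transformations / summaries
# ---------------------------------------------------------------------------

def standardize_features(ft: FeatureTable, ddof: int = 1) -> FeatureTable:
    """Center each feature column and scale to unit sample variance.

    Zero-variance columns are centered (to exactly 0) and flagged instead of
    divided by zero.  Idempotent to numerical precision.
    """
    if ft.shape[0] < 2:
        raise IntegrityError("cannot standardize a table with fewer than 2 songs")
    if not np.all(np.isfinite(ft.values)):
        raise IntegrityError("non-finite feature values")

    mu = ft.values.mean(axis=0)
    sd = ft.values.std(axis=0, ddof=ddof)
    zero = sd == 0.0
    centered = ft.values - mu
    scaled = np.where(zero, centered, centered / np.where(zero, 1.0, sd))
    flagged = [name for j, name in enumerate(ft.feature_names) if zero[j]]
    return replace(
        ft, values=scaled, standardized=True,
        zero_variance=sorted(set(ft.zero_variance) | set(flagged)),
    )


def lower_median(counts) -> int:
    """Median of integer counts; for even n, the lower of the two middle values."""
    xs = sorted(counts)
    if not xs:
        return 0
    return xs[(len(xs) - 1) // 2]


def summarize_corpus(corpus: CorpusTable, family_map: dict[str, str]) -> CorpusSummary:
    """Breadth-and-depth summary: counts by context, region, languoid, family.

    *family_map* resolves glottocode -> language family (an input file in
    practice; Glottolog genealogy is not computed here).  Glottocodes absent
    from the map are counted under family ``"unknown"`` with a warning.
    """
    df = corpus.df
    n_songs = len(df)

    per_context = df["type"].value_counts()
    per_region = df["region"].value_counts()

    unmapped = sorted(set(df["glottocode"]) - set(family_map)) if n_songs else []
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} glottocodes missing from family map, "
            f"counted as 'unknown'", CoverageWarning, stacklevel=2,
        )
    families = df["glottocode"].map(lambda g: family_map.get(g, "unknown"))
    per_family = families.value_counts()
    n_families = int(per_family.index.nunique())

    coverage = int((pd.crosstab(df["region"], df["type"]) > 0).to_numpy().sum()) \
        if n_songs else 0

    return CorpusSummary(
        n_songs=n_songs,
        n_languoids=int(df["glottocode"].nunique()),
        n_families=n_families if n_songs else 0,
        per_context=per_context,
        context_median=lower_median(per_context.values),
        context_range=(int(per_context.min()), int(per_context.max()))
        if n_songs else (0, 0),
        per_region=per_region,
        region_median=lower_median(per_region.values),
        region_range=(int(per_region.min()), int(per_region.max()))
        if n_songs else (0, 0),
        per_family=per_family,
        region_context_coverage=coverage,
    )
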
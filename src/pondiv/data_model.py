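"""Core data containers and delimited-file I/O.

Every analysis stage consumes one (or both) of two tables:

* a pond x species abundance matrix of valve counts, with each pond assigned
  to one of exactly two regions (e.g. a Mediterranean coastal site ``CP`` and
  an Alpine plateau site ``GS``);
* a species x trait binary incidence matrix over a fixed catalogue of diatom
  functional traits (ecological guilds, life-forms, attachment modes and
  biovolume size classes).

Canonical on-disk formats are plain CSV/TSV with a header row; the region
assignment travels in a separate two-column ``pond,region`` mapping file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pondiv")

#: Fixed trait catalogue: ecological guilds (low-profile, high-profile,
#: motile, planktonic), life-forms/attachment (mobile, benthic, high/medium/
#: low attachment, mucilaginous tube, pedunculate, colonial, pioneer) and
#: biovolume size classes.  User extensions (e.g. ``BioVol_c4``) are accepted.
TRAIT_CATALOGUE: tuple[str, ...] = (
    "LowPro", "HighPro", "Motile", "Planktonic",
    "Mobile", "Benthic",
    "ATT_Hig", "ATT_Med", "ATT_Low",
    "MucoTub", "Pedunculate", "Colonial", "Pioneer",
    "BioVol_c1", "BioVol_c2", "BioVol_c3", "BioVol_c5",
)

#: Mutually exclusive ecological guilds (exactly one per species).
GUILD_TRAITS: tuple[str, ...] = ("LowPro", "HighPro", "Motile", "Planktonic")
#: Mutually exclusive biovolume classes (exactly one per species).
BIOVOL_TRAITS: tuple[str, ...] = ("BioVol_c1", "BioVol_c2", "BioVol_c3", "BioVol_c5")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class CommunityMatrix:
    """Pond x species abundance matrix (non-negative integer valve counts).

    ``counts`` is a DataFrame indexed by pond with species columns;
    ``region_of`` maps every pond to its region label.
    """

    counts: pd.DataFrame
    region_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        _check_unique(list(self.counts.index), "pond")
        _check_unique(list(self.counts.columns), "species")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("abundances must be numeric")
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at pond {self.counts.index[i]!r}, "
                f"species {self.counts.columns[j]!r}"
            )
        missing = [p for p in self.counts.index if p not in self.region_of]
        if missing:
            raise ValidationError(f"ponds missing from region map: {missing}")
        empty = self.counts.index[arr.sum(axis=1) == 0].tolist()
        if empty:
            warnings.warn(f"ponds with no positive counts: {empty}", stacklevel=3)

    # -- convenience accessors -------------------------------------------
    @property
    def ponds(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def regions(self) -> list[str]:
        # stable order of first appearance
        out: list[str] = []
        for p in self.ponds:
            r = self.region_of[p]
            if r not in out:
                out.append(r)
        return out

    def ponds_in(self, region: str) -> list[str]:
        if region not in set(self.region_of.values()):
            raise KeyError(f"unknown region: {region!r}")
        return [p for p in self.ponds if self.region_of[p] == region]

    def subset(self, ponds: Iterable[str]) -> "CommunityMatrix":
        ponds = list(ponds)
        sub = self.counts.loc[ponds]
        return CommunityMatrix(sub, {p: self.region_of[p] for p in ponds})

    def restrict(self, scope: str | Sequence[str] | None) -> "CommunityMatrix":
        """Subset by region label, explicit pond list, or None (everything)."""
        if scope is None:
            return self
        if isinstance(scope, str):
            return self.subset(self.ponds_in(scope))
        return self.subset(scope)


@dataclass
class TraitMatrix:
    """Species x trait binary incidence over the trait catalogue."""

    incidence: pd.DataFrame

    def __post_init__(self) -> None:
        self.incidence = self.incidence.copy()
        _check_unique(list(self.incidence.index), "species")
        _check_unique(list(self.incidence.columns), "trait")
        arr = self.incidence.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("trait incidence must be binary (0/1)")
        bare = self.incidence.index[arr.sum(axis=1) == 0].tolist()
        if bare:
            raise ValidationError(f"species with no traits: {bare}")

    @property
    def species(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def traits(self) -> list[str]:
        return list(self.incidence.columns)

    def restrict(self, species: Sequence[str]) -> "TraitMatrix":
        missing = [s for s in species if s not in self.incidence.index]
        if missing:
            raise ValidationError(f"species missing from trait matrix: {missing}")
        return TraitMatrix(self.incidence.loc[list(species)])


@dataclass
class AlignedDataset:
    """Community and trait matrices over an identical, identically ordered
    species list (community restricted to a scope, traits to its species)."""

    community: CommunityMatrix
    traits: TraitMatrix

    def __post_init__(self) -> None:
        if self.community.species != self.traits.species:
            raise ValidationError(
                "community and trait species lists differ or are ordered differently"
            )


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.isfinite(self.d).all():
            raise ValidationError("non-finite dissimilarity")
        if (self.d < 0).any():
            raise ValidationError("negative dissimilarity")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("nonzero diagonal")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("asymmetric distance matrix")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_region_map(path: str | Path, delimiter: str = ",") -> dict[str, str]:
    """Read a two-column ``pond,region`` CSV (header row required)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("region map needs two columns: pond, region")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_community_matrix(
    path: str | Path,
    region_map: str | Path | Mapping[str, str],
    delimiter: str = ",",
    orientation: str = "ponds_rows",
    allow_noninteger: bool = False,
) -> CommunityMatrix:
    """Read a delimited abundance table into a validated :class:`CommunityMatrix`.

    The default orientation has ponds as rows and species as columns
    (vegan convention); pass ``orientation="species_rows"`` to transpose.
    Non-integer abundances are rejected unless ``allow_noninteger`` is set,
    in which case they are rounded with a logged warning.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "species_rows":
        df = df.T
    elif orientation != "ponds_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        if not allow_noninteger:
            raise ValidationError(
                "non-integer abundances found; pass allow_noninteger=True to round"
            )
        logger.warning("non-integer abundances in %s rounded to counts", path)
    df = df.round().astype(int)
    if not isinstance(region_map, Mapping):
        region_map = read_region_map(region_map, delimiter=delimiter)
    regions = {p: region_map[p] for p in df.index if p in region_map}
    missing = [p for p in df.index if p not in region_map]
    if missing:
        raise ValidationError(f"ponds missing from region map: {missing}")
    return CommunityMatrix(df, regions)


def read_trait_matrix(path: str | Path, delimiter: str = ",") -> TraitMatrix:
    """Read a species (rows) x trait (columns) binary CSV."""
    df = pd.read_csv(path, sep=delimiter, index_col=0).astype(int)
    return TraitMatrix(df)


def write_community_matrix(
    cm: CommunityMatrix, path: str | Path, region_path: str | Path | None = None
) -> None:
    cm.counts.to_csv(path, index_label="pond")
    if region_path is not None:
        pd.DataFrame(
            {"pond": cm.ponds, "region": [cm.region_of[p] for p in cm.ponds]}
        ).to_csv(region_path, index=False)


def write_trait_matrix(tm: TraitMatrix, path: str | Path) -> None:
    tm.incidence.to_csv(path, index_label="species")


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def to_presence_absence(cm: CommunityMatrix) -> CommunityMatrix:
    """Binarize counts (1 where positive); labels and regions unchanged."""
    pa = (cm.counts > 0).astype(int)
    return CommunityMatrix(pa, dict(cm.region_of))


def align(
    cm: CommunityMatrix,
    tm: TraitMatrix,
    scope: str | Sequence[str] | None = None,
) -> AlignedDataset:
    """Restrict community to ``scope`` and traits to the species that occur
    there (positive total count), identically ordered.

    Species present in the scoped community but absent from the trait matrix
    raise an error naming them.
    """
    sub = cm.restrict(scope)
    present = [s for s in sub.species if sub.counts[s].sum() > 0]
    missing = [s for s in present if s not in tm.incidence.index]
    if missing:
        raise ValidationError(f"species missing from trait matrix: {missing}")
    community = CommunityMatrix(sub.counts[present], dict(sub.region_of))
    return AlignedDataset(community=community, traits=tm.restrict(present))
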
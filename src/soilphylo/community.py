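"""Site x species occurrence matrices and site environment tables.

The occurrence matrix is strictly binary (presence/absence); the environment
table carries the soil base-cation concentration (cmol(+)/kg, the edaphic
gradient), a three-level geological-formation factor, and optional covariates
(phosphorus, aluminum, pH).  ``align_dataset`` joins both with a tree sample
into one consistently ordered triple, which every downstream computation
assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import Phylogeny, TreeSample, prune_to

logger = logging.getLogger(__name__)

FORMATIONS = ("Solimoes", "Ica", "Terrace")
_FORMATION_ALIASES = {
    "solimoes": "Solimoes", "solimões": "Solimoes",
    "ica": "Ica", "içá": "Ica", "iça": "Ica", "icá": "Ica",
    "terrace": "Terrace", "terraces": "Terrace",
}

__all__ = [
    "CommunityMatrix",
    "FORMATIONS",
    "read_community",
    "read_environment",
    "align_dataset",
    "merge_taxa",
]


@dataclass
class CommunityMatrix:
    """Binary site x species occurrence table."""

    sites: tuple[str, ...]
    taxa: tuple[str, ...]
    values: np.ndarray  # (n_sites, n_taxa) int8 in {0, 1}

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.sites), len(self.taxa)):
            raise ValueError("occurrence matrix shape does not match site/taxon labels")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("occurrence matrix must be binary (0/1)")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        self.values = v.astype(np.int8)
        self.sites = tuple(self.sites)
        self.taxa = tuple(self.taxa)

    @property
    def richness(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sites), columns=list(self.taxa))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())

    def subset(self, sites: Sequence[str] | None = None,
               taxa: Sequence[str] | None = None) -> "CommunityMatrix":
        df = self.to_frame()
        if sites is not None:
            df = df.loc[list(sites)]
        if taxa is not None:
            df = df[list(taxa)]
        return CommunityMatrix.from_frame(df)


def read_community(path: str | Path, *, transpose: bool = False,
                   coerce_counts: bool = False, sep: str = ",") -> CommunityMatrix:
    """Read a site x taxon occurrence CSV (taxa in columns unless ``transpose``).

    Positive integer counts are coerced to presence (1) only when
    ``coerce_counts`` is set, with a logged warning; otherwise non-binary
    values are an error.
    """
    df = pd.read_csv(path, index_col=0, sep=sep)
    if transpose:
        df = df.T
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValueError(f"non-numeric occurrence column(s): {list(bad)}")
    if np.isnan(arr.astype(float)).any():
        raise ValueError("missing values in occurrence matrix")
    if (arr < 0).any():
        raise ValueError("negative values in occurrence matrix")
    nonbinary = arr > 1
    if nonbinary.any():
        if not coerce_counts:
            raise ValueError(
                f"{int(nonbinary.sum())} cell(s) hold counts > 1; "
                "pass coerce_counts=True to reduce to presence/absence"
            )
        logger.warning("coerced %d count cell(s) > 1 to presence", int(nonbinary.sum()))
        arr = np.minimum(arr, 1)
    frac = arr - np.floor(arr)
    if (frac != 0).any():
        raise ValueError("non-integer values in occurrence matrix")
    return CommunityMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                           arr.astype(np.int8))


def read_environment(path: str | Path, *, sep: str = ",") -> pd.DataFrame:
    """Read and validate the per-site environment table.

    Requires columns ``site``, ``base_cation`` (cmol(+)/kg, strictly positive
    so the log transform is defined) and ``formation`` (normalized
    case-insensitively to Solimoes / Ica / Terrace); optional ``phosphorus``
    (mg/kg), ``aluminum`` (cmol(+)/kg) and ``pH`` are carried through.
    """
    df = pd.read_csv(path, sep=sep, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = {"site", "base_cation", "formation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing column(s): {sorted(missing)}")
    df["site"] = df["site"].astype(str).str.strip()
    if df["site"].duplicated().any():
        raise ValueError(f"duplicate site id(s): "
                         f"{sorted(df.loc[df['site'].duplicated(), 'site'])}")
    bad = df.loc[~(df["base_cation"] > 0), "site"]
    if len(bad):
        raise ValueError(f"base_cation must be > 0; offending site(s): {list(bad)}")
    norm = df["formation"].astype(str).str.strip().str.lower().map(_FORMATION_ALIASES)
    unknown = df.loc[norm.isna(), "formation"]
    if len(unknown):
        raise ValueError(
            f"unknown formation level(s): {sorted(set(unknown))}; "
            f"expected one of {FORMATIONS}"
        )
    df["formation"] = pd.Categorical(norm, categories=FORMATIONS)
    return df.set_index("site", drop=False)


def validate_environment(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory environment frame (same rules as :func:`read_environment`)."""
    import io as _io
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_environment(buf)  # type: ignore[arg-type]


def merge_taxa(community: CommunityMatrix, merges: dict[str, Sequence[str]]) -> CommunityMatrix:
    """Collapse groups of taxa into single terminals (presence = union).

    ``merges`` maps the merged name to the taxa it absorbs, e.g. species the
    study treats as a single taxon.
    """
    df = community.to_frame()
    for new, olds in merges.items():
        olds = [o for o in olds if o in df.columns]
        if not olds:
            continue
        merged = df[olds].max(axis=1)
        df = df.drop(columns=olds)
        df[new] = merged
    return CommunityMatrix.from_frame(df)


def align_dataset(
    community: CommunityMatrix,
    env: pd.DataFrame,
    trees: TreeSample,
    *,
    drop_empty_taxa: bool = True,
    missing_taxa: str = "drop",
) -> tuple[CommunityMatrix, pd.DataFrame, TreeSample]:
    """Join community, environment and trees on shared sites/taxa.

    Sites are restricted to the community/environment intersection (mismatches
    logged); taxa to the tree tip set (``missing_taxa='drop'`` drops and logs,
    ``'error'`` raises); trees are pruned to the matrix taxa.  The returned
    site and taxon orders are fixed (sorted) and identical across all
    downstream outputs; the operation is idempotent.
    """
    comm_sites, env_sites = set(community.sites), set(env["site"])
    sites = sorted(comm_sites & env_sites)
    if not sites:
        raise ValueError("no sites shared between community matrix and environment table")
    lost = comm_sites.symmetric_difference(env_sites)
    if lost:
        logger.warning("dropping %d site(s) absent from one input: %s", len(lost), sorted(lost))

    tips = trees.tip_labels
    absent = [t for t in community.taxa if t not in tips]
    if absent:
        if missing_taxa == "error":
            raise ValueError(f"taxa absent from trees: {absent}")
        logger.warning("dropping %d taxon(a) absent from trees: %s", len(absent), absent)
    taxa = sorted(t for t in community.taxa if t in tips)

    comm = community.subset(sites=sites, taxa=taxa)
    if drop_empty_taxa:
        occupied = comm.values.sum(axis=0) > 0
        if not occupied.all():
            dropped = [t for t, keep in zip(comm.taxa, occupied) if not keep]
            logger.info("dropping %d unobserved taxon(a): %s", len(dropped), dropped)
            comm = comm.subset(taxa=[t for t, k in zip(comm.taxa, occupied) if k])

    env_out = env.loc[sites].copy()
    if set(comm.taxa) != tips:
        pruned = TreeSample([prune_to(t, comm.taxa) for t in trees])
    else:
        pruned = trees
    return comm, env_out, pruned
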
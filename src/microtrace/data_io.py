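"""OTU-table data model, on-disk formats and preprocessing filters.

The in-memory convention is sample-major: an :class:`OtuTable` wraps a
``pandas.DataFrame`` with one row per sample and one column per OTU.  On
disk the table is transposed (rows = OTUs, columns = samples), the common
amplicon-pipeline orientation, with an optional trailing ``taxonomy``
column holding a semicolon-delimited ranked lineage per OTU.

Preprocessing follows the standard amplicon workflow: OTUs at high
relative abundance in kit-control samples are flagged as likely reagent
contaminants, counts are rarefied (uniform subsampling without
replacement) to a common depth, and rare OTUs are removed by a
prevalence filter before source apportionment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "flag_contaminants",
    "rarefy",
    "prevalence_filter",
    "family_source_composition",
]

SAMPLE_TYPES = ("skin", "surface", "air", "control")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class OtuTableError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with OTU ids as columns.
    mode:
        ``"counts"`` (non-negative integers) or ``"relative"`` (each
        non-empty row sums to 1).
    taxonomy:
        Optional map OTU id -> semicolon-delimited lineage string
        (e.g. ``"k__Bacteria;...;f__Moraxellaceae;g__Acinetobacter"``).
    """

    data: pd.DataFrame
    mode: str = "counts"
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise OtuTableError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise OtuTableError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise OtuTableError(f"duplicate OTU id {dup!r}")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            raise OtuTableError("non-finite abundance value")
        if (values < 0).any():
            sample = self.data.index[np.where(values < 0)[0][0]]
            raise OtuTableError(f"negative abundance in sample {sample!r}")
        if self.mode == "counts":
            if not np.allclose(values, np.round(values)):
                sample = self.data.index[
                    np.where(~np.isclose(values, np.round(values)))[0][0]
                ]
                raise OtuTableError(f"non-integer count in sample {sample!r}")
            self.data = self.data.astype(np.int64)
        else:
            sums = values.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0))
            if bad.any():
                sample = self.data.index[np.where(bad)[0][0]]
                raise OtuTableError(
                    f"relative abundances in sample {sample!r} sum to "
                    f"{sums[bad][0]:.6g}, expected 1"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        return self.data.loc[sample_id]

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)].copy(), self.mode, self.taxonomy)

    def subset_otus(self, otu_ids) -> "OtuTable":
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        tax = {o: self.taxonomy[o] for o in keep if o in self.taxonomy} if self.taxonomy else None
        return OtuTable(self.data[keep].copy(), self.mode, tax)

    def drop_otus(self, otu_ids) -> "OtuTable":
        drop = set(otu_ids)
        return self.subset_otus([o for o in self.otu_ids if o not in drop])

    def to_relative(self) -> "OtuTable":
        """Convert counts to per-sample relative abundances (all-zero rows stay zero)."""
        values = self.data.to_numpy(dtype=float)
        totals = values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, values / totals, 0.0)
        return OtuTable(
            pd.DataFrame(rel, index=self.data.index, columns=self.data.columns),
            "relative",
            self.taxonomy,
        )

    # -- taxonomy --------------------------------------------------------
    def family(self, otu_id: str) -> str | None:
        """Family-rank name of an OTU, or None if unassigned."""
        if self.taxonomy is None or otu_id not in self.taxonomy:
            return None
        return parse_family(self.taxonomy[otu_id])

    def families(self) -> pd.Series:
        """Series OTU id -> family name (NaN where unassigned)."""
        if self.taxonomy is None:
            raise OtuTableError("table has no taxonomy")
        return pd.Series(
            {o: parse_family(self.taxonomy.get(o, "")) for o in self.otu_ids},
            dtype=object,
        )


def parse_family(lineage: str) -> str | None:
    """Extract the family rank from a semicolon-delimited greengenes-style lineage."""
    if not lineage:
        return None
    ranks = [r.strip() for r in lineage.split(";")]
    for rank in ranks:
        if rank.startswith("f__"):
            name = rank[3:].strip()
            return name or None
    # fall back to positional rank 5 (kingdom..family) for bare lineages
    if len(ranks) >= 5 and not any(r[:3] in _RANK_PREFIXES for r in ranks if len(r) >= 3):
        return ranks[4] or None
    return None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_otu_table(table: OtuTable, path) -> None:
    """Write a table as TSV, rows = OTUs, columns = samples, optional taxonomy column."""
    out = table.data.T.copy()
    out.index.name = "otu_id"
    if table.taxonomy is not None:
        out["taxonomy"] = [table.taxonomy.get(o, "") for o in out.index]
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_otu_table(path, mode: str = "counts") -> OtuTable:
    """Read a TSV OTU table (rows = OTUs, header row of sample ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise OtuTableError(f"duplicate OTU id {dup!r} in {path}")
    taxonomy = None
    if raw.shape[1] and raw.columns[-1].lower() == "taxonomy":
        tax_col = raw.pop(raw.columns[-1]).fillna("")
        taxonomy = {otu: lin for otu, lin in tax_col.items() if lin}
    if raw.isna().any().any():
        row = raw.index[raw.isna().any(axis=1)][0]
        raise OtuTableError(f"ragged or missing values in row {row!r} of {path}")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise OtuTableError(f"non-numeric value in {path}: {exc}") from exc
    data = values.T
    data.index.name = None
    data.columns.name = None
    return OtuTable(data, mode=mode, taxonomy=taxonomy)


METADATA_COLUMNS = ["type", "residence", "site", "individual", "season"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample metadata contract and normalise dtypes.

    Skin samples carry an ``individual`` label, non-skin samples must not;
    every non-control sample carries an ordinal ``season``.
    """
    meta = meta.copy()
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise OtuTableError(f"metadata missing column {col!r}")
    bad_type = ~meta["type"].isin(SAMPLE_TYPES)
    if bad_type.any():
        raise OtuTableError(f"unknown sample type {meta['type'][bad_type].iloc[0]!r}")
    meta["season"] = pd.array(
        pd.to_numeric(meta["season"], errors="coerce"), dtype="Int64"
    )
    skin = meta["type"] == "skin"
    if meta.loc[skin, "individual"].isna().any():
        sid = meta.index[skin & meta["individual"].isna()][0]
        raise OtuTableError(f"skin sample {sid!r} has no individual")
    if meta.loc[~skin, "individual"].notna().any():
        sid = meta.index[~skin & meta["individual"].notna()][0]
        raise OtuTableError(f"non-skin sample {sid!r} has an individual label")
    noncontrol = meta["type"] != "control"
    if meta.loc[noncontrol, "season"].isna().any():
        sid = meta.index[noncontrol & meta["season"].isna()][0]
        raise OtuTableError(f"sample {sid!r} has no season")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"individual": str})
    return validate_metadata(meta)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    seen: set[str] = set()
    for tip in tree.tips():
        if tip.name in seen:
            raise OtuTableError(f"duplicate leaf label {tip.name!r}")
        seen.add(tip.name)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def flag_contaminants(table: OtuTable, control_ids, threshold: float = 0.05) -> set[str]:
    """OTUs at >= `threshold` relative abundance in at least one control sample.

    The boundary is inclusive: an OTU at exactly 5% of a control's reads is
    flagged under the default threshold.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise OtuTableError("cannot apply contaminant rule with no control samples")
    missing = [c for c in control_ids if c not in table.data.index]
    if missing:
        raise OtuTableError(f"control sample {missing[0]!r} not in table")
    if not 0 < threshold <= 1:
        raise OtuTableError("threshold must be in (0, 1]")
    controls = table.data.loc[control_ids].to_numpy(dtype=float)
    totals = controls.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, controls / totals, 0.0)
    flagged = (rel >= threshold).any(axis=0)
    return {o for o, f in zip(table.otu_ids, flagged) if f}


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Rarefy each sample to `depth` reads by uniform subsampling without replacement.

    ``depth=None`` uses the minimum sample total (the most depauperate
    sample).  Samples below the requested depth are dropped with a warning.
    """
    if table.mode != "counts":
        raise OtuTableError("rarefaction requires a counts table")
    totals = table.data.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise OtuTableError("rarefaction depth must be >= 1")
    low = totals[totals < depth]
    if len(low):
        warnings.warn(
            f"dropping {len(low)} sample(s) below rarefaction depth {depth}: "
            + ", ".join(map(str, low.index[:10])),
            stacklevel=2,
        )
    keep = totals.index[totals >= depth]
    rng = np.random.default_rng(seed)
    rows = []
    for sid in keep:
        counts = table.data.loc[sid].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=keep, columns=table.data.columns)
    return OtuTable(out, "counts", table.taxonomy)


def prevalence_filter(table: OtuTable, min_fraction: float = 0.10) -> OtuTable:
    """Keep OTUs present (count > 0) in at least `min_fraction` of samples."""
    if not 0 <= min_fraction <= 1:
        raise OtuTableError("min_fraction must be in [0, 1]")
    presence = (table.data.to_numpy() > 0).mean(axis=0)
    keep = [o for o, p in zip(table.otu_ids, presence) if p >= min_fraction]
    return table.subset_otus(keep)


def preprocess_study(
    table: OtuTable,
    meta: pd.DataFrame,
    contaminant_threshold: float = 0.05,
    depth: int | None = None,
    seed: int = 0,
) -> tuple[OtuTable, pd.DataFrame]:
    """Standard preprocessing: contaminant removal then rarefaction.

    OTUs at >= `contaminant_threshold` relative abundance in any kit
    control are removed from the table.  Non-control samples are rarefied
    to `depth` (default: the most depauperate non-control sample);
    control samples keep their remaining raw counts, since after
    contaminant removal they are typically too shallow to subsample and
    serve only as pooled negative-control sources.  Returns the cleaned
    table and the metadata restricted to surviving samples.
    """
    meta = validate_metadata(meta)
    control_ids = list(meta.index[meta["type"] == "control"])
    cleaned = table
    if control_ids:
        contaminants = flag_contaminants(table, control_ids, contaminant_threshold)
        cleaned = table.drop_otus(contaminants)
    sample_ids = [s for s in cleaned.sample_ids if s in meta.index]
    noncontrol = [s for s in sample_ids if s not in set(control_ids)]
    rarefied = rarefy(cleaned.subset_samples(noncontrol), depth=depth, seed=seed)
    keep_controls = [s for s in control_ids if s in cleaned.data.index]
    if keep_controls:
        combined = pd.concat(
            [rarefied.data, cleaned.data.loc[keep_controls, rarefied.data.columns]]
        )
        out = OtuTable(combined, "counts", cleaned.taxonomy)
    else:
        out = rarefied
    return out, meta.loc[out.sample_ids]


def family_source_composition(
    table: OtuTable, family_lists: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-sample summed relative abundance of OTUs from each source's indicator families.

    ``family_lists`` maps a source environment name (e.g. ``"human skin"``)
    to a set of bacterial family names.  Sources with overlapping lists are
    scored independently, so columns need not sum to <= 1.
    """
    if table.taxonomy is None:
        raise OtuTableError("family composition requires taxonomy")
    rel = table if table.mode == "relative" else table.to_relative()
    fams = rel.families()
    out = {}
    for source, families in family_lists.items():
        members = [o for o in rel.otu_ids if fams[o] in set(families)]
        out[source] = rel.data[members].sum(axis=1) if members else pd.Series(
            0.0, index=rel.data.index
        )
    return pd.DataFrame(out, index=rel.data.index)
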
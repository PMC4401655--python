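"""Readers/writers for the pipeline's TSV tables, plus the taxonomy
summary and dipterocarp/non-dipterocarp frequency tables.

All files are UTF-8, tab-delimited, '.' decimal, with a header row and a
leading ID column.  Matrices are written samples-as-rows.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LEVELS, CountMatrix, DistanceMatrix, HostAssignment, OccurrenceMatrix
from .errors import ValidationError
from .stats import fisher_exact_two_sided, holm_adjust, round_half_away

RANKS = ("phylum", "order", "family", "genus")


def default_ecm_whitelist() -> frozenset:
    """Shipped whitelist of putatively ectomycorrhizal basidiomycete families."""
    text = importlib.resources.files("hostpref.data").joinpath("ecm_families.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass
class TaxonomyTable:
    """Fungal OTU taxonomy with an ECM flag.

    ``is_ecm`` is True only for OTUs whose family (or genus) is on the
    whitelist AND whose phylum is Basidiomycota; the ECM guild targeted
    here is basidiomycetous.
    """

    table: pd.DataFrame  # index otu_id; columns phylum/order/family/genus/is_ecm

    def __post_init__(self):
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate OTU id {dup!r} in taxonomy table")
        for rank in RANKS:
            if rank not in self.table.columns:
                self.table[rank] = pd.NA
        bad = self.table["is_ecm"] & (self.table["phylum"] != "Basidiomycota")
        if bad.any():
            raise ValidationError(
                f"OTU {self.table.index[bad][0]!r} flagged ECM but not Basidiomycota"
            )

    @property
    def otu_ids(self) -> pd.Index:
        return self.table.index

    def select(self, phylum=None, ecm_only: bool = False) -> pd.Index:
        """OTU ids matching a phylum and/or the ECM flag (taxon subset filters)."""
        mask = pd.Series(True, index=self.table.index)
        if phylum is not None:
            mask &= self.table["phylum"] == phylum
        if ecm_only:
            mask &= self.table["is_ecm"].astype(bool)
        return self.table.index[mask]


# ---------------------------------------------------------------------------
# readers / writers


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(df, state="raw")


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_occurrence(path) -> OccurrenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return OccurrenceMatrix(df)


def write_occurrence(occ: OccurrenceMatrix, path) -> None:
    occ.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path, whitelist=None) -> TaxonomyTable:
    """Read a taxonomy TSV and derive the ECM flag from a family/genus whitelist."""
    if whitelist is None:
        whitelist = default_ecm_whitelist()
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = pd.NA
    on_list = df["family"].isin(whitelist) | df["genus"].isin(whitelist)
    df["is_ecm"] = (on_list & (df["phylum"] == "Basidiomycota")).astype(bool)
    return TaxonomyTable(df)


def make_taxonomy(records: pd.DataFrame, whitelist=None) -> TaxonomyTable:
    """Build a TaxonomyTable from an in-memory frame (same flagging as read_taxonomy)."""
    if whitelist is None:
        whitelist = default_ecm_whitelist()
    df = records.copy()
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = pd.NA
    on_list = df["family"].isin(whitelist) | df["genus"].isin(whitelist)
    df["is_ecm"] = (on_list & (df["phylum"] == "Basidiomycota")).astype(bool)
    return TaxonomyTable(df)


def read_hosts(path) -> HostAssignment:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if "is_dipterocarp" in df.columns:
        df["is_dipterocarp"] = df["is_dipterocarp"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    return HostAssignment(df)


def write_hosts(hosts: HostAssignment, path) -> None:
    hosts.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_distance(path, kind: str = "generic") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix(df, kind=kind)


def write_distance(dm: DistanceMatrix, path) -> None:
    dm.data.rename_axis("label").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# summaries


def summarize_taxonomy(tax: TaxonomyTable) -> pd.DataFrame:
    """Counts and percentage shares of OTUs per taxon at each assigned rank.

    The denominator at each rank is the number of OTUs assigned at that
    rank (unassigned OTUs are excluded); percentages are rounded half away
    from zero to one decimal.  An extra ``ecm_basidiomycota`` row reports
    the share of ECM-flagged OTUs among Basidiomycota.
    """
    if len(tax.table) == 0:
        raise ValidationError("empty taxonomy table")
    rows = []
    for rank in RANKS:
        assigned = tax.table[rank].dropna()
        assigned = assigned[assigned.astype(str).str.len() > 0]
        denom = len(assigned)
        if denom == 0:
            continue
        for taxon, n in assigned.value_counts().items():
            rows.append(
                {"rank": rank, "taxon": taxon, "n_otus": int(n), "n_assigned": denom,
                 "share_pct": round_half_away(100.0 * n / denom, 1)}
            )
    basidio = tax.table[tax.table["phylum"] == "Basidiomycota"]
    if len(basidio):
        n_ecm = int(basidio["is_ecm"].sum())
        rows.append(
            {"rank": "guild", "taxon": "ecm_basidiomycota", "n_otus": n_ecm,
             "n_assigned": len(basidio),
             "share_pct": round_half_away(100.0 * n_ecm / len(basidio), 1)}
        )
    return pd.DataFrame(rows)


def _group_frequency(present: pd.Series, samples: pd.Index) -> float:
    if len(samples) == 0:
        raise ValidationError("frequency requested for a group with zero samples")
    return float(round_half_away(100.0 * present.loc[samples].mean(), 1))


def frequency_table(
    occ: OccurrenceMatrix,
    tax: TaxonomyTable,
    hosts: HostAssignment,
    group_by: str = "family",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon occurrence frequencies in dipterocarp / non-dipterocarp /
    all samples, with Fisher-Holm significance of the dip vs non-dip split.

    Frequency = % of group samples containing at least one OTU of the
    taxon.  Each taxon gets a two-sided Fisher exact p on the 2x2
    (present/absent x dip/non-dip) table; Holm correction is applied
    across every taxon in the returned table.
    """
    if group_by not in RANKS:
        raise ValidationError(f"group_by must be one of {RANKS}")
    shared = occ.sample_ids.intersection(hosts.sample_ids)
    if len(shared) == 0:
        raise ValidationError("no samples shared between occurrence matrix and host table")
    data = occ.data.loc[shared]
    is_dip = hosts.table.loc[shared, "is_dipterocarp"].astype(bool)
    dip_samples = shared[is_dip.to_numpy()]
    nondip_samples = shared[~is_dip.to_numpy()]
    if len(dip_samples) == 0 or len(nondip_samples) == 0:
        raise ValidationError("one of the host groups has zero samples")

    tax_otus = tax.table.reindex(data.columns)
    rows = []
    for phylum in tax_otus["phylum"].dropna().unique():
        groups = [("(in total)", tax_otus.index[tax_otus["phylum"] == phylum])]
        if phylum == "Basidiomycota":
            ecm = tax_otus.index[tax_otus["is_ecm"].fillna(False).astype(bool)]
            if len(ecm):
                groups.append(("(ECM taxa)", ecm))
        if group_by != "phylum":
            sub = tax_otus[tax_otus["phylum"] == phylum]
            for taxon in sorted(sub[group_by].dropna().unique()):
                groups.append((taxon, sub.index[sub[group_by] == taxon]))
        for name, otus in groups:
            present = (data[otus].sum(axis=1) > 0).astype(int)
            a = int(present.loc[dip_samples].sum())
            b = len(dip_samples) - a
            c = int(present.loc[nondip_samples].sum())
            d = len(nondip_samples) - c
            rows.append(
                {
                    "phylum": phylum,
                    "taxon": name,
                    "total_pct": _group_frequency(present, shared),
                    "dip_pct": _group_frequency(present, dip_samples),
                    "nondip_pct": _group_frequency(present, nondip_samples),
                    "fisher_p": fisher_exact_two_sided([[a, b], [c, d]]),
                }
            )
    out = pd.DataFrame(rows)
    out["holm_p"] = holm_adjust(out["fisher_p"].to_numpy())
    out["significant"] = out["holm_p"] < alpha
    return out
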
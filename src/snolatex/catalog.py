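"""Published rubber-tree snoRNA catalogue tables, shipped as package data.

These small TSVs transcribe the published summary tables of the rubber-tree
latex snoRNA survey: the rRNA modification-site census, the filtering
cascade accounting, the 50 laticifer-abundant snoRNAs with their latex/leaf
fold changes, the 31 predicted target sites of the 13 latex-abundant guide
snoRNAs, and the regeneration-ability correlation coefficients of the 13
yield-correlated snoRNAs.  They serve as arithmetic-fidelity fixtures: the
loaders parse them into the package's data model and the summary functions
recompute the printed totals and cross-table sums.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sequences_io import SequenceError


def _load(name: str) -> pd.DataFrame:
    with resources.files("snolatex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def modification_site_counts() -> pd.DataFrame:
    """Per-rRNA counts of Nm and psi sites (LSU / SSU / 5.8S)."""
    return _load("modification_site_counts.tsv")


def filter_cascade() -> pd.DataFrame:
    """Candidate counts per analysis step and predictor category, with the
    published per-step totals."""
    return _load("filter_cascade.tsv")


def latex_abundant() -> pd.DataFrame:
    """The 50 laticifer-abundant snoRNAs (name, length, class, fold change)."""
    return _load("latex_abundant_snornas.tsv")


def target_sites() -> pd.DataFrame:
    """Predicted rRNA target sites of the latex-abundant guide snoRNAs,
    one row per (snoRNA, site)."""
    df = _load("target_sites.tsv")
    df["nucleotide"] = df["site"].str[0]
    df["position"] = df["site"].str[1:].astype(int)
    return df


def regeneration_correlations() -> pd.DataFrame:
    """Spearman coefficients of the 13 yield-correlated snoRNAs against
    the 3-h regeneration ability."""
    return _load("regeneration_correlations.tsv")


def site_census_totals() -> dict[str, int]:
    """Recomputed totals of the modification-site census."""
    df = modification_site_counts()
    return {
        "nm_total": int(df["nm_sites"].sum()),
        "psi_total": int(df["psi_sites"].sum()),
        "all_sites": int(df["nm_sites"].sum() + df["psi_sites"].sum()),
    }


def cascade_row_sums() -> pd.DataFrame:
    """Per-step category sums alongside the printed totals; the cascade is
    internally consistent iff they agree and retention telescopes down."""
    df = filter_cascade()
    categories = [c for c in df.columns if c not in ("step", "total")]
    out = df[["step", "total"]].copy()
    out["computed"] = df[categories].sum(axis=1)
    return out


def cascade_is_consistent() -> bool:
    sums = cascade_row_sums()
    telescoping = sums["total"].is_monotonic_decreasing
    return bool((sums["total"] == sums["computed"]).all() and telescoping)


def cross_table_checks() -> dict[str, bool]:
    """Cross-table sums linking the cascade, the latex-abundant list, the
    target-site table and the regeneration correlations."""
    cascade = filter_cascade().set_index("step")
    abundant = latex_abundant()
    sites = target_sites()
    regen = regeneration_correlations()
    # subfamily follows the predictor: snoScan/CDSeeker call C/D snoRNAs,
    # ACASeeker calls H/ACA (the class column mixes guide/orphan status)
    cd = abundant["predicted_using"].isin(["snoScan", "CDSeeker"]).sum()
    haca = len(abundant) - cd
    return {
        "latex_abundant_matches_cascade": int(
            cascade.loc["High expression in latex", "total"]
        )
        == len(abundant),
        "subfamily_split_22_28": (int(cd), int(haca)) == (22, 28),
        "regeneration_matches_cascade": int(
            cascade.loc["Related to latex regeneration", "total"]
        )
        == len(regen),
        "guide_snornas_with_sites": sites["snorna"].nunique() == 13,
        "psi_sites_on_u": bool(
            (sites.loc[sites.mtype == "psi", "nucleotide"] == "U").all()
        ),
    }


def target_site_summary() -> dict[str, int]:
    sites = target_sites()
    by_rrna = sites.groupby("rrna")
    return {
        "total_sites": len(sites),
        "sites_18S": int(by_rrna.size().get("18S", 0)),
        "sites_28S": int(by_rrna.size().get("28S", 0)),
        "snornas_18S": int(sites[sites.rrna == "18S"]["snorna"].nunique()),
        "snornas_28S": int(sites[sites.rrna == "28S"]["snorna"].nunique()),
    }
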
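"""Aggregation of attributed errors into rates, fold changes and profiles.

Rates divide collapsed event counts by the total number of analyzable
sequenced bases per sample; replicate templates then give a mean and standard
deviation per enzyme/condition.  The effect of a base modification is the
relative fold change (M - S)/S of each substitution subtype, where M is the
rate on modified RNA and S on unmodified RNA (0 = no change, -1 = complete
suppression).  Condition comparisons use a two-sided Welch t-test with
Bonferroni adjustment of the significance level when multiple comparisons
are made.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .refgen import Amplicon

_RNA = str.maketrans("ACGT", "ACGU")

ERROR_TYPES = ("substitution", "deletion", "insertion")


def compute_rates(
    events: pd.DataFrame,
    totals: dict[str, int],
    by: tuple[str, ...] = ("strand", "type"),
    template_col: str = "template",
) -> pd.DataFrame:
    """Per-template error rates: collapsed events / total analyzable bases.

    *events* must carry a template column (every value present in *totals*);
    *totals* maps template label -> total analyzable sequenced bases.  Groups
    absent from the events get an explicit zero row for the standard error
    types so that empty categories surface as rate 0 rather than silently
    disappearing.
    """
    for tpl, n in totals.items():
        if n <= 0:
            raise ValueError(f"zero total bases for template {tpl!r}")
    if len(events) and template_col not in events.columns:
        raise ValueError(f"events table lacks a {template_col!r} column")
    if len(events):
        unknown = set(events[template_col]) - set(totals)
        if unknown:
            raise ValueError(f"templates without base totals: {sorted(unknown)}")

    rows = []
    grouped = (
        events.groupby([template_col, *by], observed=True).size()
        if len(events)
        else pd.Series(dtype=int)
    )
    for tpl in sorted(totals):
        n_bases = totals[tpl]
        keys = set()
        if len(events):
            sub = grouped.loc[[tpl]] if tpl in events[template_col].values else pd.Series(dtype=int)
            for idx, n_ev in sub.items():
                key = idx[1:] if isinstance(idx, tuple) else (idx,)
                keys.add(key)
                rows.append(
                    dict(zip([template_col, *by], [tpl, *key]))
                    | {"n_events": int(n_ev), "n_bases": n_bases, "rate": n_ev / n_bases}
                )
        if by and by[-1] == "type":  # zero rows for missing standard types
            prefix_keys = {k[:-1] for k in keys} or ({("first",)} if by == ("strand", "type") else {()})
            for prefix in prefix_keys:
                for t in ERROR_TYPES:
                    if prefix + (t,) not in keys:
                        rows.append(
                            dict(zip([template_col, *by], [tpl, *prefix, t]))
                            | {"n_events": 0, "n_bases": n_bases, "rate": 0.0}
                        )
    df = pd.DataFrame(rows, columns=[template_col, *by, "n_events", "n_bases", "rate"])
    return df.sort_values([template_col, *by]).reset_index(drop=True)


def summarize_rates(
    rate_table: pd.DataFrame,
    by: tuple[str, ...] = ("strand", "type"),
    template_col: str = "template",
) -> pd.DataFrame:
    """Mean and SD of per-template rates across replicate templates."""
    g = rate_table.groupby(list(by), observed=True)["rate"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    return out.rename(columns={"mean": "rate_mean", "std": "rate_sd", "count": "n_templates"})


def error_composition(rate_table: pd.DataFrame, strand: str | None = None) -> pd.DataFrame:
    """Percentage of total errors by type (substitution/deletion/insertion)."""
    df = rate_table if strand is None else rate_table[rate_table["strand"] == strand]
    counts = df.groupby("type", observed=True)["n_events"].sum().reindex(ERROR_TYPES, fill_value=0)
    total = counts.sum()
    pct = counts / total * 100.0 if total else counts.astype(float)
    return pd.DataFrame({"n_events": counts, "pct": pct}).reset_index()


def fold_change(M: float, S: float) -> float:
    """Relative fold change (M - S)/S of a modified vs unmodified rate."""
    if S <= 0:
        raise ValueError("fold change undefined: unmodified rate S must be > 0")
    return (M - S) / S


def fold_change_table(
    rates_m: dict[str, float], rates_s: dict[str, float]
) -> pd.DataFrame:
    """Fold change per substitution subtype; undefined entries are flagged."""
    rows = []
    for sub in sorted(set(rates_m) | set(rates_s)):
        M = rates_m.get(sub, 0.0)
        S = rates_s.get(sub, 0.0)
        try:
            fc, note = fold_change(M, S), ""
        except ValueError:
            fc, note = np.nan, "undefined: S=0"
        rows.append({"subtype": sub, "M": M, "S": S, "fold_change": fc, "note": note})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    pvalue: float
    alpha_adjusted: float
    significant: bool


def compare_conditions(
    rates_a, rates_b, n_comparisons: int = 1, alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided Welch t-test on per-template rates; Bonferroni-adjusted.

    Significance is declared iff p < alpha / n_comparisons.
    """
    a = np.asarray(list(rates_a), dtype=float)
    b = np.asarray(list(rates_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("at least 2 replicate templates per condition are required")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    adj = alpha / n_comparisons
    return ComparisonResult(float(t), float(p), adj, bool(p < adj))


_SIZE_BINS = ("1", "2", "3", "4+")


def indel_size_distribution(events: pd.DataFrame) -> pd.DataFrame:
    """Percentage of collapsed indel events by size (1, 2, 3, >=4).

    One row per indel type; rows with no events keep zero percentages and an
    n_events of 0 so empty categories are visible.
    """
    rows = []
    for kind in ("deletion", "insertion"):
        sub = events[events["type"] == kind] if len(events) else events
        n = len(sub)
        binned = {b: 0 for b in _SIZE_BINS}
        if n:
            for size in sub["length"]:
                binned["4+" if size >= 4 else str(int(size))] += 1
        row = {"type": kind, "n_events": n}
        for b in _SIZE_BINS:
            row[b] = binned[b] / n * 100.0 if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["type", "n_events", *_SIZE_BINS])


@dataclass(frozen=True)
class Hotspot:
    ref_pos: int
    count: int
    context: str


def rank_hotspots(
    events: pd.DataFrame, amplicon: Amplicon, top_k: int = 3
) -> dict[str, list[Hotspot]]:
    """Reference positions ranked by error frequency, per error type.

    Ties are broken by ascending position; each hotspot carries +/-5 bases of
    reference context.  Types with no events map to an empty list.
    """
    out: dict[str, list[Hotspot]] = {}
    seq = amplicon.sequence
    for kind in ERROR_TYPES:
        sub = events[events["type"] == kind] if len(events) else events
        if not len(sub):
            out[kind] = []
            continue
        counts = sub.groupby("ref_pos").size().reset_index(name="count")
        counts = counts.sort_values(["count", "ref_pos"], ascending=[False, True])
        out[kind] = [
            Hotspot(
                int(r.ref_pos),
                int(r.count),
                seq[max(0, int(r.ref_pos) - 5) : int(r.ref_pos) + 6],
            )
            for r in counts.head(top_k).itertuples()
        ]
    return out


@dataclass
class ContextProfile:
    """Base frequencies flanking substitution events, RNA-sense alphabet."""

    matrix: pd.DataFrame  # index: offsets -W..-1, 1..W; columns A/C/G/U
    n_events: int
    n_excluded: int
    window: int


def context_profile(
    events: pd.DataFrame, amplicon: Amplicon, window: int = 3
) -> ContextProfile:
    """Flanking-base frequency matrix around substitution events.

    Flanks are read from the reference (RNA-sense, reported with U); events
    whose window would run past the reference ends are excluded and counted.
    """
    subs = events[events["type"] == "substitution"] if len(events) else events
    offsets = [o for o in range(-window, window + 1) if o != 0]
    counts = pd.DataFrame(0, index=offsets, columns=list("ACGU"), dtype=float)
    seq = amplicon.sequence.translate(_RNA)
    n_used = n_excluded = 0
    for pos in subs["ref_pos"] if len(subs) else []:
        pos = int(pos)
        if pos - window < 0 or pos + window >= len(seq):
            n_excluded += 1
            continue
        n_used += 1
        for o in offsets:
            counts.loc[o, seq[pos + o]] += 1
    if n_used:
        counts = counts / n_used
    return ContextProfile(counts, n_used, n_excluded, window)
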
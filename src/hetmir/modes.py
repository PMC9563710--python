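"""Inheritance-mode classification of differentially expressed miRNAs.

For each miRNA and each reciprocal hybrid H, four contrasts feed the
call: H vs P1, H vs P2, P1 vs P2, and H vs A (the synthetic mid-parent).
The decision order resolves the overlaps the verbal definitions allow —
transgressive patterns are the strictly stronger statements, so they are
tested first:

1. over_dominant   — H up vs both parents
2. under_dominant  — H down vs both parents
3. hp_dominant     — H up vs exactly one parent, ns vs the other
                     (hybrid sits at the high-parent level)
4. lp_dominant     — H down vs exactly one parent, ns vs the other
5. additive        — parents differ (P1 vs P2 significant) and H ~ A
6. ambiguous       — H up vs one parent and down vs the other
7. conserved       — anything else

The order makes every one of the 3^4 possible status combinations map to
exactly one mode.  High/low parent identity is a property of the data
(which parent expresses more), not of the P1/P2 labels, so parent-label
swaps cannot flip a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import log

__all__ = ["ContrastBundle", "ModeCall", "classify_mode", "classify_all", "summarize_modes"]

MODES = (
    "additive",
    "hp_dominant",
    "lp_dominant",
    "over_dominant",
    "under_dominant",
    "conserved",
    "ambiguous",
)

NON_CONSERVED = tuple(m for m in MODES if m not in ("conserved",))


@dataclass(frozen=True)
class ContrastBundle:
    """Status of the four contrasts for one miRNA in one hybrid.

    Each status is ``up``, ``down`` or ``ns``, with the hybrid (resp. P1)
    as group 1, so ``h_vs_p1 == "up"`` means the hybrid expresses more
    than parent 1.
    """

    mirna_id: str
    hybrid: str
    h_vs_p1: str
    h_vs_p2: str
    p1_vs_p2: str
    h_vs_a: str

    def __post_init__(self) -> None:
        for name in ("h_vs_p1", "h_vs_p2", "p1_vs_p2", "h_vs_a"):
            v = getattr(self, name)
            if v not in ("up", "down", "ns"):
                raise ValueError(f"{name} must be up/down/ns, got {v!r}")


@dataclass(frozen=True)
class ModeCall:
    mirna_id: str
    hybrid: str
    mode: str
    merged_label: str = "none"  # in_H12 | in_H21 | in_both | none


def classify_mode(bundle: ContrastBundle) -> ModeCall:
    """Apply the decision order to one contrast bundle."""
    a, b = bundle.h_vs_p1, bundle.h_vs_p2
    if a == "up" and b == "up":
        mode = "over_dominant"
    elif a == "down" and b == "down":
        mode = "under_dominant"
    elif ("up" in (a, b)) and ("ns" in (a, b)):
        mode = "hp_dominant"
    elif ("down" in (a, b)) and ("ns" in (a, b)):
        mode = "lp_dominant"
    elif bundle.p1_vs_p2 != "ns" and bundle.h_vs_a == "ns":
        mode = "additive"
    elif {a, b} == {"up", "down"}:
        mode = "ambiguous"
    else:
        mode = "conserved"
    return ModeCall(bundle.mirna_id, bundle.hybrid, mode)


def _is_de_anywhere(row: pd.Series) -> bool:
    """DE in at least one of the five pairwise comparisons."""
    pairwise = [
        row["h12_vs_p1"], row["h12_vs_p2"],
        row["h21_vs_p1"], row["h21_vs_p2"],
        row["p1_vs_p2"],
    ]
    return any(s != "ns" for s in pairwise)


def classify_all(status: pd.DataFrame) -> pd.DataFrame:
    """Classify every miRNA in both hybrids and merge reciprocal calls.

    Parameters
    ----------
    status
        One row per miRNA with columns ``mirna_id`` and the six contrast
        statuses ``h12_vs_p1``, ``h12_vs_p2``, ``h21_vs_p1``,
        ``h21_vs_p2``, ``p1_vs_p2``, ``h12_vs_a``, ``h21_vs_a``.

    Returns
    -------
    DataFrame with columns mirna_id, hybrid, mode, merged_label; two rows
    per miRNA that is DE in at least one pairwise comparison (others are
    conserved by definition and excluded from summaries).
    ``merged_label`` is ``in_both`` iff the same non-conserved mode holds
    in both hybrids, ``in_H12``/``in_H21`` when only that hybrid carries
    a non-conserved mode, ``none`` otherwise.
    """
    required = {
        "mirna_id", "h12_vs_p1", "h12_vs_p2", "h21_vs_p1", "h21_vs_p2",
        "p1_vs_p2", "h12_vs_a", "h21_vs_a",
    }
    missing = required - set(status.columns)
    if missing:
        raise ValueError(f"missing contrast columns: {sorted(missing)}")

    rows = []
    n_skipped = 0
    for _, r in status.iterrows():
        if not _is_de_anywhere(r):
            n_skipped += 1
            continue
        calls = {}
        for hybrid, p1c, p2c, ac in (
            ("H12", "h12_vs_p1", "h12_vs_p2", "h12_vs_a"),
            ("H21", "h21_vs_p1", "h21_vs_p2", "h21_vs_a"),
        ):
            calls[hybrid] = classify_mode(
                ContrastBundle(
                    r["mirna_id"], hybrid, r[p1c], r[p2c], r["p1_vs_p2"], r[ac]
                )
            )
        m12, m21 = calls["H12"].mode, calls["H21"].mode
        if m12 == m21 and m12 != "conserved":
            merged = "in_both"
        elif m12 != "conserved" and m21 == "conserved":
            merged = "in_H12"
        elif m21 != "conserved" and m12 == "conserved":
            merged = "in_H21"
        else:
            merged = "none"
        for hybrid in ("H12", "H21"):
            c = calls[hybrid]
            rows.append(
                {
                    "mirna_id": c.mirna_id,
                    "hybrid": hybrid,
                    "mode": c.mode,
                    "merged_label": merged,
                }
            )
    log.info("classify_all: %d miRNAs classified, %d conserved (excluded)",
             len(rows) // 2, n_skipped)
    return pd.DataFrame(rows, columns=["mirna_id", "hybrid", "mode", "merged_label"])


def summarize_modes(mode_table: pd.DataFrame) -> pd.DataFrame:
    """Unique-miRNA counts per inheritance-mode category.

    A miRNA holding the same mode in both hybrids counts once; the
    ``additive`` and ``non_additive`` totals are unique-miRNA counts as
    well.  (A miRNA carrying two *different* non-conserved modes across
    the hybrids contributes to both categories.)
    """
    counts = {m: 0 for m in MODES if m != "conserved"}
    if len(mode_table):
        for m in counts:
            counts[m] = mode_table.loc[mode_table["mode"] == m, "mirna_id"].nunique()
    non_add = mode_table.loc[
        ~mode_table["mode"].isin(("conserved", "additive")), "mirna_id"
    ].nunique() if len(mode_table) else 0
    rows = [{"category": m, "n_mirnas": n} for m, n in counts.items()]
    rows.append({"category": "non_additive_total", "n_mirnas": non_add})
    rows.append({
        "category": "demir_total",
        "n_mirnas": mode_table["mirna_id"].nunique() if len(mode_table) else 0,
    })
    return pd.DataFrame(rows)
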
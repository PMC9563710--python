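"""Egg-laying phenotypes: egg number, clutch size, mid-parent value, heterosis.

A lay record is a binary vector over days (1 = egg laid).  A clutch is a
maximal run of consecutive laying days; egg number is the sum of the
record, which equals the sum of clutch lengths.  Heterosis in percent is

    100 * (F1 - MPV) / MPV,   MPV = (P1 + P2) / 2,

the relative superiority of the hybrid mean over the mid-parent value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import log

__all__ = ["clutch_sizes", "trait_summary", "heterosis_percent", "heterosis_table"]


@dataclass(frozen=True)
class HeterosisInput:
    f1: float
    p1: float
    p2: float


def clutch_sizes(record) -> list[int]:
    """Lengths of maximal runs of consecutive laying days, in order.

    Sum of the returned lengths equals the record's egg number.
    """
    rec = np.asarray(record)
    if rec.size and not np.isin(rec, (0, 1)).all():
        raise ValueError("lay record entries must be 0 or 1")
    if rec.size == 0:
        return []
    padded = np.concatenate(([0], rec, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return (ends - starts).tolist()


def _per_hen_traits(records: pd.DataFrame) -> pd.DataFrame:
    day_cols = [c for c in records.columns if c not in ("hen_id", "genotype")]
    rows = []
    for _, r in records.iterrows():
        runs = clutch_sizes(r[day_cols].to_numpy(dtype=float).astype(int))
        rows.append(
            {
                "hen_id": r["hen_id"],
                "genotype": r["genotype"],
                "egg_number": int(sum(runs)),
                "mean_clutch": float(np.mean(runs)) if runs else 0.0,
                "max_clutch": int(max(runs)) if runs else 0,
            }
        )
    return pd.DataFrame(rows)


def trait_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean/SD/n for egg number and clutch size, plus MPV.

    ``records`` is a table with hen_id, genotype and one 0/1 column per
    day.  Clutch size per hen is summarized as the mean run length (the
    max is reported alongside).  A genotype with a single hen gets SD 0
    and ``single_hen`` flagged.  The mid-parent value row ``MPV`` is the
    average of the P1 and P2 genotype means.
    """
    hens = _per_hen_traits(records)
    if hens.empty:
        raise ValueError("no lay records")
    rows = []
    for g, sub in hens.groupby("genotype", sort=False):
        single = len(sub) == 1
        if single:
            log.warning("trait_summary: genotype %s has a single hen; SD set to 0", g)
        rows.append(
            {
                "genotype": g,
                "n": len(sub),
                "egg_number_mean": sub["egg_number"].mean(),
                "egg_number_sd": 0.0 if single else sub["egg_number"].std(ddof=1),
                "clutch_mean": sub["mean_clutch"].mean(),
                "clutch_sd": 0.0 if single else sub["mean_clutch"].std(ddof=1),
                "max_clutch_mean": sub["max_clutch"].mean(),
                "single_hen": single,
            }
        )
    out = pd.DataFrame(rows)
    for parent in ("P1", "P2"):
        if parent not in set(out["genotype"]):
            raise ValueError(f"genotype {parent} absent; cannot form mid-parent value")
    p = out.set_index("genotype")
    mpv = {
        "genotype": "MPV",
        "n": 0,
        "egg_number_mean": (p.loc["P1", "egg_number_mean"] + p.loc["P2", "egg_number_mean"]) / 2,
        "egg_number_sd": np.nan,
        "clutch_mean": (p.loc["P1", "clutch_mean"] + p.loc["P2", "clutch_mean"]) / 2,
        "clutch_sd": np.nan,
        "max_clutch_mean": (p.loc["P1", "max_clutch_mean"] + p.loc["P2", "max_clutch_mean"]) / 2,
        "single_hen": False,
    }
    return pd.concat([out, pd.DataFrame([mpv])], ignore_index=True)


def heterosis_percent(f1: float, p1: float, p2: float) -> float:
    """Mid-parent heterosis in percent: 100 * (F1 - (P1+P2)/2) / ((P1+P2)/2).

    Zero iff the hybrid mean equals the mid-parent value; symmetric in the
    parents and invariant to rescaling all three means.
    """
    midparent = (p1 + p2) / 2.0
    if midparent <= 0:
        raise ValueError("mid-parent value must be positive")
    return 100.0 * (f1 - midparent) / midparent


def heterosis_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Heterosis percentages per trait and hybrid from a trait summary."""
    s = summary.set_index("genotype")
    rows = []
    for trait, col in (("egg_number", "egg_number_mean"), ("clutch_size", "clutch_mean")):
        for hybrid in ("H12", "H21"):
            if hybrid not in s.index:
                continue
            rows.append(
                {
                    "trait": trait,
                    "hybrid": hybrid,
                    "heterosis_pct": heterosis_percent(
                        s.loc[hybrid, col], s.loc["P1", col], s.loc["P2", col]
                    ),
                }
            )
    return pd.DataFrame(rows)
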
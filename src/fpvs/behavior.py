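"""Lexical-decision task (LDT) analysis.

Covers list assembly bookkeeping, the mean+3SD outlier trim, the natural-
log RT transform, and descriptive pre/post competition summaries per
category and learning method (per-participant means first, then group mean
and a paired t statistic).  Mixed-effects modeling is deliberately out of
scope — the tidy tables this module emits are the input to external
GLMM/LMM tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdtDesign",
    "assemble_ldt",
    "trim_outliers",
    "log_rt",
    "competition_summary",
]


@dataclass(frozen=True)
class LdtDesign:
    """Composition of the lexical-decision list.

    Defaults: 32 novel words, 32 real-word neighbors (ON1L), 32 pseudoword
    neighbors (PW1L), 32 unlearned words and 80 fillers, presented in 4
    blocks of 52 (208 trials total).
    """

    category_counts: dict[str, int] = field(
        default_factory=lambda: {
            "novel": 32,
            "ON1L": 32,
            "PW1L": 32,
            "unlearned": 32,
            "filler_word": 40,
            "filler_pw": 40,
        }
    )
    n_blocks: int = 4
    block_size: int = 52

    def __post_init__(self) -> None:
        total = sum(self.category_counts.values())
        if total == 0:
            raise ValueError("empty design: all category counts are zero")
        if total != self.n_blocks * self.block_size:
            raise ValueError(
                f"category counts sum to {total}, expected "
                f"{self.n_blocks} x {self.block_size} = "
                f"{self.n_blocks * self.block_size}"
            )


def assemble_ldt(design: LdtDesign, seed: int) -> pd.DataFrame:
    """Assemble a randomized trial order.

    Each category's items are spread as evenly as possible across blocks
    (balanced composition), then shuffled within block.  Reproducible
    under ``seed``.  Returns columns block, trial, category, item.
    """
    rng = np.random.default_rng(seed)
    blocks: list[list[tuple[str, str]]] = [[] for _ in range(design.n_blocks)]
    for cat, count in design.category_counts.items():
        items = [f"{cat}_{i:03d}" for i in range(count)]
        rng.shuffle(items)
        # deal round-robin over a shuffled block order for even composition
        order = rng.permutation(design.n_blocks)
        for i, item in enumerate(items):
            blocks[order[i % design.n_blocks]].append((cat, item))
    rows = []
    for b, block in enumerate(blocks):
        idx = rng.permutation(len(block))
        for t, j in enumerate(idx):
            cat, item = block[j]
            rows.append(
                {"block": b + 1, "trial": t + 1, "category": cat, "item": item}
            )
    return pd.DataFrame(rows)


GROUP_COLS = ["category", "method", "session"]


def trim_outliers(
    table: pd.DataFrame,
    group_cols: list[str] | None = None,
    n_sd: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials with RT above mean + 3 SD of their group.

    Groups are category x method x session; SD uses the n-1 denominator
    and the rule is applied once (not iterated).  Groups of size 1 are kept
    (SD undefined) and noted in the report.  Returns (kept rows, report
    with per-group removal counts).
    """
    group_cols = group_cols or GROUP_COLS
    if table.empty:
        raise ValueError("empty trial table")
    keep_mask = pd.Series(True, index=table.index)
    report_rows = []
    for key, grp in table.groupby(group_cols, sort=False):
        if len(grp) == 1:
            report_rows.append(
                dict(zip(group_cols, key), n=1, removed=0, note="single trial; kept")
            )
            continue
        m = grp["rt_ms"].mean()
        sd = grp["rt_ms"].std(ddof=1)
        cutoff = m + n_sd * sd
        bad = grp.index[grp["rt_ms"] > cutoff]
        keep_mask.loc[bad] = False
        report_rows.append(
            dict(zip(group_cols, key), n=len(grp), removed=len(bad), note="")
        )
    return table.loc[keep_mask].copy(), pd.DataFrame(report_rows)


def log_rt(table: pd.DataFrame) -> pd.DataFrame:
    """Add a natural-log RT column (``log_rt``); RTs must be positive.

    Millisecond summaries of log-RT means back-transform via exp.
    """
    if (table["rt_ms"] <= 0).any():
        raise ValueError("non-positive RT encountered")
    out = table.copy()
    out["log_rt"] = np.log(out["rt_ms"])
    return out


def competition_summary(
    table: pd.DataFrame,
    correct_only: bool = True,
) -> pd.DataFrame:
    """Descriptive pre/post contrast per category x method.

    Per-participant mean RTs are computed first, then the group mean per
    session, the signed delta (post - pre), accuracy per session, and a
    paired two-sided t statistic on the participant means.  Participants
    missing a session in a cell are excluded from that cell's contrast
    with a warning.  RT means use correct trials only by default
    (configurable); accuracy uses all trials.
    """
    rows = []
    for (cat, method), grp in table.groupby(["category", "method"], sort=False):
        acc = grp.groupby("session")["correct"].mean()
        rt_grp = grp[grp["correct"]] if correct_only else grp
        per_part = (
            rt_grp.groupby(["participant", "session"])["rt_ms"].mean().unstack()
        )
        for col in ("pre", "post"):
            if col not in per_part.columns:
                per_part[col] = np.nan
        complete = per_part.dropna(subset=["pre", "post"])
        n_dropped = len(per_part) - len(complete)
        if n_dropped:
            warnings.warn(
                f"{cat}/{method}: {n_dropped} participant(s) missing a "
                "session; excluded from the paired contrast",
                stacklevel=2,
            )
        if len(complete) >= 2:
            t_stat, p_val = stats.ttest_rel(complete["post"], complete["pre"])
        else:
            t_stat, p_val = np.nan, np.nan
        rows.append(
            {
                "category": cat,
                "method": method,
                "n_participants": len(complete),
                "rt_pre_ms": complete["pre"].mean(),
                "rt_post_ms": complete["post"].mean(),
                "rt_delta_ms": (complete["post"] - complete["pre"]).mean(),
                "acc_pre": acc.get("pre", np.nan),
                "acc_post": acc.get("post", np.nan),
                "t_paired": float(t_stat),
                "p_paired": float(p_val),
            }
        )
    return pd.DataFrame(rows)
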
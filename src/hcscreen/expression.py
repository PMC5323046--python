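"""Replicate expression-ratio averaging and fold-change gating."""

from __future__ import annotations

import numpy as np
import pandas as pd

UP_CUT = 1.3
DOWN_CUT = 0.7


def average_ratios(tables, cv_cutoff: float = 0.5,
                   log_scale: bool = False) -> pd.DataFrame:
    """Average per-gene knockdown/control ratios over replicate experiments.

    ``tables`` is a list of DataFrames with ``gene`` and ``ratio`` columns
    (one per experiment).  The mean is arithmetic on the linear scale by
    default (``log_scale=True`` switches to the geometric mean).  Genes with
    a between-experiment coefficient of variation above ``cv_cutoff`` are
    QC-flagged; single-experiment genes are flagged low-n.
    """
    if not tables:
        raise ValueError("need at least one experiment table")
    frames = []
    for i, t in enumerate(tables, start=1):
        if (t["ratio"] <= 0).any():
            raise ValueError(f"experiment {i} contains non-positive ratios")
        frames.append(t[["gene", "ratio"]].assign(experiment=i))
    long = pd.concat(frames, ignore_index=True)

    def agg(grp):
        r = grp["ratio"].to_numpy(dtype=float)
        mean = float(np.exp(np.log(r).mean())) if log_scale else float(r.mean())
        cv = float(r.std(ddof=1) / r.mean()) if len(r) > 1 else np.nan
        return pd.Series({
            "mean_ratio": mean,
            "n_experiments": len(r),
            "cv": cv,
            "qc_flag": bool(len(r) > 1 and cv > cv_cutoff),
            "low_n": len(r) < 2,
        })

    out = long.groupby("gene", sort=True).apply(agg, include_groups=False)
    out = out.reset_index()
    out["n_experiments"] = out["n_experiments"].astype(int)
    return out


def threshold_de(ratios: pd.DataFrame, up_cut: float = UP_CUT,
                 down_cut: float = DOWN_CUT, strict: bool = True):
    """Partition genes into (up, down, neither) sets by their mean ratio.

    Strict inequalities by default: up iff mean > up_cut, down iff mean <
    down_cut; ``strict=False`` makes both inclusive.
    """
    mean = ratios.set_index("gene")["mean_ratio"]
    if strict:
        up = set(mean[mean > up_cut].index)
        down = set(mean[mean < down_cut].index)
    else:
        up = set(mean[mean >= up_cut].index)
        down = set(mean[mean <= down_cut].index)
    neither = set(mean.index) - up - down
    return up, down, neither


def curate_panel(ratios: pd.DataFrame, panel: list,
                 up_cut: float = UP_CUT, down_cut: float = DOWN_CUT) -> pd.DataFrame:
    """Panel table of curated genes with their class bar, in panel order.

    Panel genes absent from the ratio table are listed with missing values.
    """
    up, down, _ = threshold_de(ratios, up_cut, down_cut)
    indexed = ratios.set_index("gene")
    rows = []
    for gene in panel:
        if gene in indexed.index:
            rec = indexed.loc[gene]
            cls = "up" if gene in up else ("down" if gene in down else "neither")
            rows.append((gene, float(rec["mean_ratio"]), cls,
                         bool(rec["qc_flag"]), False))
        else:
            rows.append((gene, np.nan, "missing", False, True))
    return pd.DataFrame(rows, columns=["gene", "mean_ratio", "class",
                                       "qc_flag", "missing"])
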
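"""Spectral-count interaction scoring against a multi-bait background.

Implements the frequency-penalized D-score family: D = sqrt(APSM * (K/f)^p)
with K background baits, f the number of baits retrieving the prey and p the
number of replicate runs detecting it; the weighted variant inflates K/f by
a dispersion-derived weight >= 1, and normalization divides by the score at
a chosen background percentile so that 1.0 is the high-confidence boundary.
HCIPs are records with normalized weighted score >= 1 and APSM >= 2.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContractError

log = logging.getLogger(__name__)

HCIP_WDN_MIN = 1.0
HCIP_APSM_MIN = 2.0


def aggregate_runs(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-run counts to per-(bait, prey) APSM and reproducibility.

    APSM is the mean spectral count over all of the bait's runs (undetected
    runs count as zero); ``p`` is the number of runs the prey was detected
    in.  Duplicate (bait, prey, run) rows are an error.
    """
    required = {"bait", "prey", "run", "counts"}
    if not required.issubset(raw.columns):
        raise ContractError(f"run table needs columns {sorted(required)}")
    if raw.duplicated(["bait", "prey", "run"]).any():
        dupes = raw[raw.duplicated(["bait", "prey", "run"], keep=False)]
        raise ContractError(
            f"duplicate (bait, prey, run) entries: {dupes.head().to_dict('records')}")
    runs_per_bait = raw.groupby("bait")["run"].nunique()
    grp = raw.groupby(["bait", "prey"])["counts"]
    stats = grp.agg(total="sum", detected=lambda c: int((c > 0).sum()))
    stats = stats.reset_index()
    stats["n_runs"] = stats["bait"].map(runs_per_bait)
    stats["apsm"] = stats["total"] / stats["n_runs"]
    stats["p"] = stats["detected"].clip(upper=stats["n_runs"])
    return stats[["bait", "prey", "apsm", "p", "n_runs"]]


def score_wdn(stats: pd.DataFrame, background=None, weighted: bool = True,
              norm_percentile: float = 98.0,
              baits_of_interest=None) -> pd.DataFrame:
    """Score every (bait, prey) record against the background bait set.

    ``background`` is the set of baits forming the frequency background
    (default: every bait in ``stats``); it must contain at least 10 baits.
    Returns one record per pair with D, WD, normalized WD^N and the HCIP
    flag (WD^N >= 1 and APSM >= 2).
    """
    if {"bait", "prey", "apsm", "p"} - set(stats.columns):
        stats = aggregate_runs(stats)
    background = set(background) if background is not None \
        else set(stats["bait"])
    if len(background) < 10:
        raise ContractError("background must contain at least 10 baits")
    k = len(background)

    bg = stats[stats["bait"].isin(background) & (stats["apsm"] > 0)]
    freq = bg.groupby("prey")["bait"].nunique()
    apsm_mean = bg.groupby("prey")["apsm"].mean()
    apsm_sd = bg.groupby("prey")["apsm"].std(ddof=1)

    sel = stats if baits_of_interest is None \
        else stats[stats["bait"].isin(baits_of_interest)]
    records = []
    for rec in sel.itertuples(index=False):
        f = int(freq.get(rec.prey, 0))
        if f == 0:
            log.info("prey %s absent from background; using f=1", rec.prey)
            f = 1
        mean = float(apsm_mean.get(rec.prey, rec.apsm))
        sd = float(apsm_sd.get(rec.prey, np.nan))
        weight = max(1.0, sd / mean) if np.isfinite(sd) and mean > 0 else 1.0
        p = int(rec.p)
        d = float(np.sqrt(rec.apsm * (k / f) ** p))
        ratio = (k / f) * (weight if weighted else 1.0)
        wd = float(np.sqrt(rec.apsm * ratio ** p))
        records.append((rec.bait, rec.prey, float(rec.apsm), f, p, weight,
                        d, wd))
    out = pd.DataFrame(records, columns=["bait", "prey", "apsm", "frequency",
                                         "reproducibility", "weight",
                                         "d_score", "wd_score"])
    divisor = float(np.percentile(out["wd_score"], norm_percentile)) \
        if len(out) else 1.0
    if divisor <= 0:
        divisor = 1.0
    out["wdn_score"] = out["wd_score"] / divisor
    out["is_hcip"] = (out["wdn_score"] >= HCIP_WDN_MIN) \
        & (out["apsm"] >= HCIP_APSM_MIN)
    return out


def export_network(hcips: pd.DataFrame, annotations: dict | None,
                   path) -> nx.Graph:
    """Write the HCIP network as a tab-separated edge list and return it.

    Nodes carry a ``prey_class`` attribute from ``annotations`` (prey ->
    class; unknown preys are 'orphan'); edge display weights are WD^N
    clamped to [1, 15].  Baits with zero HCIPs still appear as nodes.
    """
    annotations = annotations or {}
    graph = nx.Graph()
    for bait in sorted(set(hcips["bait"])):
        graph.add_node(bait, role="bait", prey_class="bait")
    edges = hcips[hcips["is_hcip"]].sort_values(["bait", "prey"])
    rows = []
    for rec in edges.itertuples(index=False):
        cls = annotations.get(rec.prey, "orphan")
        weight = float(np.clip(rec.wdn_score, 1.0, 15.0))
        graph.add_node(rec.prey, role="prey", prey_class=cls)
        graph.add_edge(rec.bait, rec.prey, wdn_score=float(rec.wdn_score),
                       display_weight=weight)
        rows.append((rec.bait, rec.prey, float(rec.wdn_score), weight, cls))
    table = pd.DataFrame(rows, columns=["bait", "prey", "wdn_score",
                                        "display_weight", "prey_class"])
    header = pd.DataFrame({"bait": sorted(set(hcips["bait"]))})
    with open(path, "w") as fh:
        fh.write("# baits: " + ",".join(header["bait"]) + "\n")
        table.to_csv(fh, sep="\t", index=False)
    return graph


def load_network(path) -> nx.Graph:
    """Read an edge list written by :func:`export_network`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# baits:"):
            raise ContractError("not a network file written by export_network")
        baits = [b for b in first.split(":", 1)[1].strip().split(",") if b]
        table = pd.read_csv(fh, sep="\t")
    graph = nx.Graph()
    for bait in baits:
        graph.add_node(bait, role="bait", prey_class="bait")
    for rec in table.itertuples(index=False):
        graph.add_node(rec.prey, role="prey", prey_class=rec.prey_class)
        graph.add_edge(rec.bait, rec.prey, wdn_score=float(rec.wdn_score),
                       display_weight=float(rec.display_weight))
    return graph
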
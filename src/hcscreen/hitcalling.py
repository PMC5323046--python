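"""Selection cascade for the screen.

Primary hit calling by the SD criterion on both spot parameters, candidate
ranking with the top-10 / multi-marker union, cytotoxicity filtering,
siRNA-deconvolution validation, treatment-response classification and the
ANOVA/Bonferroni significance helper.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

log = logging.getLogger(__name__)

DEFAULT_K = {"WIPI2": 3.0, "ATG12": 3.0, "LC3B": 2.0, "GABARAP": 2.0,
             "STX17": 2.0}


@dataclass
class HitThresholds:
    """Per-marker SD multipliers and pass-rule switches.

    The deviation bands are additive on the fold scale: a condition passes
    upward when value > 1 + k*SD(sicon) and downward when value <
    1 - k*SD(sicon).
    """

    k: dict = field(default_factory=lambda: dict(DEFAULT_K))
    default_k: float = 2.0
    require_both_parameters: bool = True
    direction: str = "either"  # increase | decrease | either

    def k_for(self, marker: str) -> float:
        k = self.k.get(marker, self.default_k)
        if k <= 0:
            raise ValueError("SD multiplier must be > 0")
        return k


@dataclass
class ToxicityParams:
    observables: tuple = ("n_cells", "nucleus_intensity", "nucleus_area",
                          "cytoplasm_intensity", "cytoplasm_area")
    cutoff: float = 3.0
    max_toxic_sirnas_per_gene: int = 1


VERDICT_COLUMNS = ["gene", "sirna", "marker", "treatment",
                   "value_spots", "value_iss", "sd_spots", "sd_iss",
                   "direction", "is_hit", "score", "stage", "rule_trail"]


def _passes(value_spots, value_iss, sd_spots, sd_iss, k,
            require_both=True):
    """(passes, direction) of the SD criterion on both parameters."""
    up_s = value_spots > 1.0 + k * sd_spots
    up_i = value_iss > 1.0 + k * sd_iss
    dn_s = value_spots < 1.0 - k * sd_spots
    dn_i = value_iss < 1.0 - k * sd_iss
    if require_both:
        if up_s and up_i:
            return True, "increase"
        if dn_s and dn_i:
            return True, "decrease"
    else:
        if up_s or up_i:
            return True, "increase"
        if dn_s or dn_i:
            return True, "decrease"
    return False, "none"


def call_primary_hits(normalized: pd.DataFrame,
                      thresholds: HitThresholds | None = None) -> pd.DataFrame:
    """Apply the SD criterion per (gene, siRNA, marker, treatment) condition.

    A condition is a hit for a marker iff both spots/cell and ISS/cell
    deviate from 1.0 by more than k*SD(sicon) in the same direction, with k
    the marker's SD multiplier.  Conditions missing either parameter are
    skipped with a log message.  Control-class rows are ignored.
    """
    thresholds = thresholds or HitThresholds()
    test = normalized[~normalized["gene"].isin(
        ["sicon", "positive", "negative", "mock"])]
    wide = test.pivot_table(
        index=["gene", "sirna", "marker", "treatment"],
        columns="parameter", values=["value", "control_sd"], aggfunc="first")

    rows = []
    for idx, rec in wide.iterrows():
        gene, sirna, marker, treatment = idx
        vs = rec.get(("value", "spots_per_cell"), np.nan)
        vi = rec.get(("value", "iss_per_cell"), np.nan)
        ss = rec.get(("control_sd", "spots_per_cell"), np.nan)
        si = rec.get(("control_sd", "iss_per_cell"), np.nan)
        if not (np.isfinite(vs) and np.isfinite(vi)):
            log.info("skipping %s/%s/%s: missing a spot parameter",
                     gene, sirna, marker)
            continue
        k = thresholds.k_for(marker)
        hit, direction = _passes(vs, vi, ss, si, k,
                                 thresholds.require_both_parameters)
        if hit and thresholds.direction != "either" \
                and direction != thresholds.direction:
            hit, direction = False, "none"
        score = max(abs(math.log(vs)) if vs > 0 else np.inf,
                    abs(math.log(vi)) if vi > 0 else np.inf)
        trail = (f"k={k:g}; spots={vs:.3f} iss={vi:.3f} "
                 f"bands=1±{k:g}·({ss:.3f},{si:.3f}) -> "
                 f"{'hit ' + direction if hit else 'not a hit'}")
        rows.append((gene, sirna, marker, treatment, vs, vi, ss, si,
                     direction, hit, score,
                     "primary_hit" if hit else "not_hit", trail))
    return pd.DataFrame(rows, columns=VERDICT_COLUMNS)


def rank_candidates(verdicts: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top-N hits per marker plus every gene hitting more than one marker.

    The ranking statistic is the maximal |log(value)| over both spot
    parameters.  Ties at rank N are all kept.  Markers with fewer than N
    hits keep everything, with a log message.
    """
    hits = verdicts[verdicts["is_hit"]].copy()
    if hits.empty:
        return hits.assign(selected_by=pd.Series(dtype=str))

    multi = (hits.groupby("gene")["marker"].nunique() > 1)
    multi_genes = set(multi[multi].index)

    selected = []
    for marker, grp in hits.groupby("marker"):
        grp = grp.sort_values("score", ascending=False)
        if len(grp) < top_n:
            log.info("marker %s has only %d hits (< top %d); keeping all",
                     marker, len(grp), top_n)
            cut = grp
        else:
            threshold_score = grp["score"].iloc[top_n - 1]
            cut = grp[grp["score"] >= threshold_score]  # keep rank-N ties
        cut = cut.assign(selected_by="top10")
        rest = grp.loc[grp.index.difference(cut.index)]
        extra = rest[rest["gene"].isin(multi_genes)].assign(
            selected_by="multi_marker")
        selected.append(pd.concat([cut, extra]))
    out = pd.concat(selected, ignore_index=True)
    out.loc[out["gene"].isin(multi_genes) & (out["selected_by"] == "top10"),
            "selected_by"] = "top10+multi_marker"
    return out


def flag_toxicity(wells: pd.DataFrame,
                  params: ToxicityParams | None = None) -> pd.DataFrame:
    """Flag cytotoxic siRNAs from per-well morphology summaries.

    For every test siRNA the replicate-mean of each observable is compared
    with the same plate's per-well sicon distribution by a robust z score
    (median / scaled MAD); any observable beyond the cutoff flags the
    siRNA.  Returns one row per (siRNA, marker, plate) with the triggering
    observables.
    """
    params = params or ToxicityParams()
    sicon = wells[wells["control_class"] == "sicon"]
    rows = []
    for (plate, marker), grp in wells[wells["control_class"] == "test"].groupby(
            ["plate", "marker"]):
        ctl = sicon[(sicon["plate"] == plate) & (sicon["marker"] == marker)]
        center = {o: float(ctl[o].median()) for o in params.observables}
        scale = {}
        for o in params.observables:
            mad = float((ctl[o] - center[o]).abs().median())
            scale[o] = 1.4826 * mad if mad > 0 else float(ctl[o].std(ddof=1)) or 1.0
        for (gene, sirna), cond in grp.groupby(["gene", "sirna"]):
            triggered = []
            for o in params.observables:
                z = (float(cond[o].mean()) - center[o]) / scale[o]
                if abs(z) > params.cutoff:
                    triggered.append(f"{o}:z={z:.1f}")
            rows.append((gene, sirna, marker, plate, bool(triggered),
                         ";".join(triggered)))
    return pd.DataFrame(rows, columns=["gene", "sirna", "marker", "plate",
                                       "toxic", "observables"])


def validate_deconvolution(passes, toxic) -> str:
    """Deconvolution verdict for one gene/marker from 4 individual siRNAs.

    ``passes`` and ``toxic`` are length-4 boolean vectors.  Validated iff
    at least 3 of 4 siRNAs pass when none is toxic, or at least 2 of the
    remaining 3 when exactly one is toxic; two or more toxic siRNAs exclude
    the gene.
    """
    passes = [bool(p) for p in passes]
    toxic = [bool(t) for t in toxic]
    if len(passes) != 4 or len(toxic) != 4:
        raise ContractError("deconvolution requires exactly 4 siRNAs per gene")
    n_toxic = sum(toxic)
    if n_toxic >= 2:
        return "excluded_toxicity"
    clean_passes = sum(p for p, t in zip(passes, toxic) if not t)
    needed = 3 if n_toxic == 0 else 2
    return "validated" if clean_passes >= needed else "not_validated"


def deconvolute(verdicts: pd.DataFrame,
                toxicity: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply the deconvolution rule over a per-siRNA verdict table.

    ``verdicts`` comes from :func:`call_primary_hits` on the deconvolution
    screen (4 siRNAs per gene and marker).  A same-direction constraint is
    enforced: the passing siRNAs counted for a gene/marker must agree on
    the majority direction of its hits.
    """
    tox_map = {}
    if toxicity is not None:
        for rec in toxicity.itertuples(index=False):
            tox_map[(rec.gene, rec.sirna, rec.marker)] = bool(rec.toxic)

    rows = []
    for (gene, marker, treatment), grp in verdicts.groupby(
            ["gene", "marker", "treatment"]):
        grp = grp.sort_values("sirna")
        if len(grp) != 4:
            raise ContractError(
                f"{gene}/{marker}: expected 4 siRNAs, got {len(grp)}")
        toxic = [tox_map.get((gene, s, marker), False) for s in grp["sirna"]]
        dirs = grp.loc[grp["is_hit"], "direction"]
        majority = dirs.mode().iloc[0] if len(dirs) else "none"
        passes = [bool(h) and d == majority
                  for h, d in zip(grp["is_hit"], grp["direction"])]
        stage = validate_deconvolution(passes, toxic)
        trail = (f"passes={[int(p) for p in passes]} "
                 f"toxic={[int(t) for t in toxic]} -> {stage}")
        rows.append((gene, marker, treatment, majority, passes, toxic,
                     stage, trail))
    return pd.DataFrame(rows, columns=["gene", "marker", "treatment",
                                       "direction", "sirna_passes",
                                       "sirna_toxic", "stage", "rule_trail"])


@dataclass
class TreatmentResponse:
    category: str
    missing_arms: list


def classify_treatment_response(sd_pass: dict, significant: dict | None = None,
                                arms=("DMSO", "Torin1", "BafA1")) -> TreatmentResponse:
    """Categorize a gene/marker by which treatment arms pass the SD criterion.

    ``sd_pass`` maps treatment -> bool (SD criterion vs sicon within the
    same treatment); ``significant`` maps treatment -> bool (ANOVA vs
    control).  Conditions that pass no SD criterion but are statistically
    significant are kept as 'significant-only' candidates.
    """
    significant = significant or {}
    missing = [a for a in arms if a not in sd_pass]
    if missing:
        log.warning("treatment arms missing: %s", missing)
    p = {a: bool(sd_pass.get(a, False)) for a in arms}
    if p["DMSO"] and p["Torin1"]:
        cat = "DMSO+Torin1"
    elif p["DMSO"]:
        cat = "DMSO"
    elif p["Torin1"]:
        cat = "Torin1"
    elif p["BafA1"]:
        cat = "BafA1"
    elif any(bool(significant.get(a, False)) for a in arms):
        cat = "significant-only"
    else:
        cat = "none"
    return TreatmentResponse(cat, missing)


def significance_vs_control(group, control, n_groups: int = 1):
    """One-way ANOVA of a group against control with Bonferroni correction.

    Returns ``(adjusted_p, stars)`` where stars follow the p<0.05 / 0.01 /
    0.001 convention.  With zero within-group variance the test degenerates:
    identical groups give p=1, separated constant groups give p=0.
    """
    g = np.asarray(group, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(g) < 2 or len(c) < 2:
        raise ValueError("need at least 2 values per group")
    if g.std(ddof=1) == 0 and c.std(ddof=1) == 0:
        raw = 1.0 if np.isclose(g.mean(), c.mean()) else 0.0
    else:
        raw = float(stats.f_oneway(g, c).pvalue)
    adj = min(1.0, raw * max(1, int(n_groups)))
    if adj < 0.001:
        stars = "***"
    elif adj < 0.01:
        stars = "**"
    elif adj < 0.05:
        stars = "*"
    else:
        stars = ""
    return adj, stars
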
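"""Relative qPCR quantification and ChIP percent-input.

Relative mRNA levels are computed against the geometric mean of three
reference genes (ACTB, HMBS, TBP by default) with a configurable
amplification efficiency; knockdown QC applies the strict 0.65 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

DEFAULT_REFERENCES = frozenset({"ACTB", "HMBS", "TBP"})


@dataclass
class CtTable:
    """Long-format Ct measurements: (sample, gene, replicate, ct)."""

    data: pd.DataFrame
    reference_genes: set = field(default_factory=lambda: set(DEFAULT_REFERENCES))
    efficiency: float = 2.0

    def __post_init__(self):
        required = {"sample", "gene", "replicate", "ct"}
        if not required.issubset(self.data.columns):
            raise ContractError(f"Ct table needs columns {sorted(required)}")
        if (self.data["ct"] <= 0).any():
            raise ContractError("Ct values must be > 0")
        if not 1.0 < self.efficiency <= 2.0:
            raise ContractError("efficiency must be in (1, 2]")

    def mean_ct(self, sample: str, gene: str) -> float:
        sel = self.data[(self.data["sample"] == sample)
                        & (self.data["gene"] == gene)]
        if sel.empty:
            raise ContractError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(sel["ct"].mean())


def _normalized_expression(ct: CtTable, target: str, sample: str,
                           average: str) -> float:
    refs = sorted(ct.reference_genes)
    if not refs:
        raise ContractError("at least one reference gene is required")
    e = ct.efficiency
    if average == "ct":
        ct_t = ct.mean_ct(sample, target)
        ref_ct = np.mean([ct.mean_ct(sample, r) for r in refs])
        return float(e ** (-(ct_t - ref_ct)))
    if average == "linear":
        sub = ct.data[ct.data["sample"] == sample]
        reps = sorted(sub["replicate"].unique())
        vals = []
        for rep in reps:
            r = sub[sub["replicate"] == rep]
            t = r[r["gene"] == target]["ct"]
            rs = [float(r[r["gene"] == g]["ct"].mean()) for g in refs
                  if not r[r["gene"] == g].empty]
            if t.empty or len(rs) != len(refs):
                continue
            vals.append(e ** (-(float(t.mean()) - np.mean(rs))))
        if not vals:
            raise ContractError(
                f"no complete replicate for {target!r} in sample {sample!r}")
        return float(np.mean(vals))
    raise ValueError("average must be 'ct' or 'linear'")


def relative_expression(ct: CtTable, target: str, condition: str,
                        control: str, average: str = "ct") -> float:
    """Fold expression of ``target`` in ``condition`` relative to ``control``.

    Per sample, expression = E^(-Ct_target) normalized to the geometric mean
    of the reference-gene expressions, which on the Ct scale is
    E^-(Ct_target - mean(Ct_refs)).  Replicates are averaged on the Ct scale
    by default (``average='ct'``); ``'linear'`` averages the per-replicate
    linear quantities instead.
    """
    num = _normalized_expression(ct, target, condition, average)
    den = _normalized_expression(ct, target, control, average)
    return num / den


def knockdown_qc(levels, cutoff: float = 0.65):
    """Strict knockdown QC: pass iff relative level < cutoff.

    ``levels`` maps siRNA id -> relative mRNA level vs sicon.  Returns a
    ``(table, pass_fraction)`` pair.
    """
    s = pd.Series(levels, dtype=float)
    table = pd.DataFrame({
        "level": s,
        "passed": s < cutoff,  # strictly below the cutoff
    })
    table.index.name = "sirna"
    frac = float(table["passed"].mean()) if len(table) else float("nan")
    return table, frac


def chip_percent_input(ct_ip, ct_input, input_fraction: float = 0.01):
    """ChIP signal as percent of input via Ct differences.

    The input Ct is first adjusted to the full-input equivalent
    (Ct_input - log2(1/input_fraction)); the result is
    100 * input_fraction * 2^(Ct_input_adjusted - Ct_IP).
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ContractError("input_fraction must be in (0, 1]")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    adjusted = ct_input - np.log2(1.0 / input_fraction)
    out = 100.0 * input_fraction * 2.0 ** (adjusted - ct_ip)
    return float(out) if out.ndim == 0 else out


def normalize_percent_input(percent_input, control_key: str):
    """Divide percent-input values by the matched control (MOCK or IgG)."""
    s = pd.Series(percent_input, dtype=float)
    if control_key not in s.index:
        raise ContractError(f"control condition {control_key!r} not measured")
    ctl = s[control_key]
    if ctl <= 0:
        raise ContractError(f"control percent-input is not positive: {ctl}")
    return s / ctl
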
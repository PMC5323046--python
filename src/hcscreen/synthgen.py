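"""Synthetic inputs for every pipeline stage.

Generates 384-well plate layouts with embedded controls, per-well spot
summaries drawn from an overdispersed generative model, rendered two-channel
well images with ground truth, qPCR Ct tables, AP-MS spectral-count runs and
replicate expression-ratio tables.  Everything is deterministic for a fixed
seed: a single master seed derives independent per-well substreams.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, LayoutError

MARKERS = ("WIPI2", "ATG12", "LC3B", "GABARAP", "STX17")
CONTROL_CLASSES = ("sicon", "positive", "negative", "mock")
REFERENCE_GENES = ("ACTB", "HMBS", "TBP")

_ROW_LETTERS = string.ascii_uppercase


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> e.g. 'A01'."""
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


def _substream(master_seed: int, *tokens) -> np.random.Generator:
    """Deterministic per-item RNG derived from the master seed."""
    key = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


# ---------------------------------------------------------------------------
# Effect model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Baseline:
    """Control-level parameters of the generative well model."""

    cells_per_well: float = 150.0
    spots_per_cell: float = 20.0
    spot_intensity: float = 50.0        # mean integrated intensity of one spot
    spot_dispersion: float = 10.0       # negative-binomial size parameter
    intensity_shape: float = 4.0        # gamma shape of per-spot intensity
    well_noise_sd: float = 0.04         # log-sd of per-well multiplicative noise
    nucleus_intensity: float = 500.0
    nucleus_area: float = 80.0
    cytoplasm_intensity: float = 120.0
    cytoplasm_area: float = 900.0
    morphology_cv: float = 0.03


@dataclass(frozen=True)
class ToxicEffect:
    """Observable consequences of a cytotoxic siRNA."""

    cell_count_fold: float = 0.2
    morphology_fold: float = 0.5


@dataclass
class EffectModel:
    """Ground-truth effects planted into a synthetic screen.

    ``gene_effects`` maps a gene symbol (or a ``(gene, marker)`` pair for
    marker-specific effects) to a pair of fold-changes on spots/cell and
    ISS/cell.  Genes absent from the map default to fold 1.0.  ``knockdown``
    maps siRNA ids to residual mRNA fractions in [0, 1]; an siRNA with
    residual r expresses a fraction (1 - r) of the full phenotype on the
    log-fold scale.
    """

    gene_effects: dict = field(default_factory=dict)
    toxic_sirnas: dict = field(default_factory=dict)
    knockdown: dict = field(default_factory=dict)
    baseline: Baseline = field(default_factory=Baseline)
    seed: int = 0
    positive_fold: tuple = (3.0, 3.0)
    negative_fold: tuple = (0.35, 0.35)
    treatment_folds: dict = field(default_factory=lambda: {
        "none": 1.0, "DMSO": 1.0, "Torin1": 2.0, "BafA1": 2.5,
    })

    def __post_init__(self):
        for key, (fs, fi) in self.gene_effects.items():
            if fs <= 0 or fi <= 0:
                raise ValueError(f"fold-changes must be > 0 (gene {key!r})")
        for sirna, frac in self.knockdown.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"residual fraction out of [0, 1] for {sirna!r}")

    def effect(self, gene: str, marker: str) -> tuple:
        """(spot fold, ISS fold) for a gene under a marker."""
        if (gene, marker) in self.gene_effects:
            return self.gene_effects[(gene, marker)]
        return self.gene_effects.get(gene, (1.0, 1.0))


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = [
    "plate", "well", "row", "col", "gene", "sirna",
    "control_class", "treatment", "replicate", "marker",
]


@dataclass
class PlateLayout:
    """Well -> (gene, siRNA, control class, treatment, replicate) assignment."""

    wells: pd.DataFrame

    def __post_init__(self):
        missing = set(LAYOUT_COLUMNS) - set(self.wells.columns)
        if missing:
            raise LayoutError(f"layout table missing columns: {sorted(missing)}")

    @property
    def plates(self):
        return list(dict.fromkeys(self.wells["plate"]))

    def test_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["control_class"] == "test"]


def _gene_names(n_genes) -> list:
    if isinstance(n_genes, int):
        return [f"GENE{i + 1:03d}" for i in range(n_genes)]
    return list(n_genes)


def make_screen_layout(
    n_genes,
    markers=MARKERS,
    sirnas_per_gene: int = 1,
    seed: int = 0,
    treatments=("none",),
    replicates: int = 4,
    n_sicon: int = 16,
    n_positive: int = 8,
    n_negative: int = 8,
    n_mock: int = 4,
    plate_shape=(16, 24),
) -> PlateLayout:
    """Lay out a screen over 384-well plates.

    Each (marker, treatment) combination gets its own plate series; every
    plate carries non-targeting (sicon), positive, negative and mock control
    wells, and each (gene, siRNA) condition occupies ``replicates`` wells on
    a single plate.  ``sirnas_per_gene`` is 1 for the pooled primary screen
    or 4 for the deconvolution screen.
    """
    genes = _gene_names(n_genes)
    if len(genes) < 1:
        raise LayoutError("need at least one gene")
    if sirnas_per_gene not in (1, 4):
        raise LayoutError("sirnas_per_gene must be 1 (pool) or 4 (deconvolution)")
    if n_sicon < 8:
        raise LayoutError("every plate needs at least 8 sicon wells")

    n_rows, n_cols = plate_shape
    capacity = n_rows * n_cols
    n_control = n_sicon + n_positive + n_negative + n_mock
    per_plate = (capacity - n_control) // replicates
    if per_plate < 1:
        raise LayoutError(
            f"plate capacity exceeded: {n_control} control wells + "
            f"{replicates} replicate wells do not fit on a {n_rows}x{n_cols} plate"
        )

    conditions = [
        (g, f"{g}_pool" if sirnas_per_gene == 1 else f"{g}_si{j + 1}")
        for g in genes
        for j in range(sirnas_per_gene)
    ]
    all_coords = [(r, c) for r in range(n_rows) for c in range(n_cols)]

    records = []
    for marker in markers:
        for treatment in treatments:
            chunks = [conditions[i:i + per_plate]
                      for i in range(0, len(conditions), per_plate)]
            for p_idx, chunk in enumerate(chunks):
                plate = f"{marker}-{treatment}-P{p_idx + 1:02d}"
                rng = _substream(seed, "layout", plate)
                order = rng.permutation(len(all_coords))
                coords = [all_coords[i] for i in order]
                cursor = 0

                def take():
                    nonlocal cursor
                    rc = coords[cursor]
                    cursor += 1
                    return rc

                for cls, n in (("sicon", n_sicon), ("positive", n_positive),
                               ("negative", n_negative), ("mock", n_mock)):
                    for rep in range(n):
                        r, c = take()
                        records.append((plate, well_name(r, c), r, c, cls, cls,
                                        cls, treatment, rep + 1, marker))
                for gene, sirna in chunk:
                    for rep in range(replicates):
                        r, c = take()
                        records.append((plate, well_name(r, c), r, c, gene,
                                        sirna, "test", treatment, rep + 1,
                                        marker))
    return PlateLayout(pd.DataFrame(records, columns=LAYOUT_COLUMNS))


# ---------------------------------------------------------------------------
# Well-level simulation
# ---------------------------------------------------------------------------

WELL_SUMMARY_COLUMNS = LAYOUT_COLUMNS + [
    "n_cells", "spots_per_cell", "iss_per_cell",
    "nucleus_intensity", "nucleus_area",
    "cytoplasm_intensity", "cytoplasm_area",
]


def _condition_folds(model: EffectModel, gene: str, sirna: str,
                     control_class: str, marker: str) -> tuple:
    if control_class == "positive":
        return model.positive_fold
    if control_class == "negative":
        return model.negative_fold
    if control_class in ("sicon", "mock"):
        return (1.0, 1.0)
    fs, fi = model.effect(gene, marker)
    residual = model.knockdown.get(sirna, 0.0)
    # residual mRNA attenuates the phenotype on the log-fold scale
    expo = 1.0 - residual
    return (fs ** expo, fi ** expo)


def simulate_well_table(layout: PlateLayout, model: EffectModel) -> pd.DataFrame:
    """Per-well summaries drawn from the generative model, bypassing imaging.

    Cell counts are Poisson, spots/cell is negative-binomial per cell, and
    ISS/cell is a sum of gamma-distributed per-spot intensities; gene effects
    scale the respective means.  Toxic siRNAs reduce cell counts and shift
    nucleus/cytoplasm morphology summaries.
    """
    b = model.baseline
    rows = []
    for rec in layout.wells.itertuples(index=False):
        rng = _substream(model.seed, "well", rec.plate, rec.well)
        fs, fi = _condition_folds(model, rec.gene, rec.sirna,
                                  rec.control_class, rec.marker)
        treat = model.treatment_folds.get(rec.treatment, 1.0)

        tox = model.toxic_sirnas.get(rec.sirna)
        cell_fold = tox.cell_count_fold if tox else 1.0
        morph_fold = tox.morphology_fold if tox else 1.0

        n_cells = int(rng.poisson(b.cells_per_well * cell_fold))
        wf_spots = float(np.exp(rng.normal(0.0, b.well_noise_sd)))
        wf_int = float(np.exp(rng.normal(0.0, b.well_noise_sd)))

        if n_cells == 0:
            spc = iss = np.nan
        else:
            spot_mean = b.spots_per_cell * fs * treat * wf_spots
            r = b.spot_dispersion
            counts = rng.negative_binomial(r, r / (r + spot_mean), n_cells)
            total_spots = int(counts.sum())
            spc = total_spots / n_cells
            int_mean = b.spot_intensity * (fi / fs) * wf_int
            k = b.intensity_shape
            iss = float(rng.gamma(k, int_mean / k, total_spots).sum()) / n_cells

        cv = b.morphology_cv
        morph = {
            "nucleus_intensity": b.nucleus_intensity,
            "nucleus_area": b.nucleus_area,
            "cytoplasm_intensity": b.cytoplasm_intensity,
            "cytoplasm_area": b.cytoplasm_area,
        }
        morph_vals = {
            key: float(rng.normal(mean * morph_fold, mean * cv))
            for key, mean in morph.items()
        }
        rows.append((*rec, n_cells, spc, iss,
                     morph_vals["nucleus_intensity"], morph_vals["nucleus_area"],
                     morph_vals["cytoplasm_intensity"],
                     morph_vals["cytoplasm_area"]))
    return pd.DataFrame(rows, columns=WELL_SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_well_image(
    n_cells: int,
    spots_per_cell: int,
    size: int = 256,
    seed: int = 0,
    nucleus_radius: float = 6.5,
    cytoplasm_radius: float = 20.0,
    nucleus_level: float = 0.85,
    cytoplasm_level: float = 0.25,
    spot_amplitude: float = 0.6,
    spot_sigma=(1.2, 2.0),
    noise_sd: float = 0.01,
    illumination_amp: float = 0.0,
    min_spot_separation: float = 11.0,
    max_attempts: int = 20000,
):
    """Render a two-channel well image plus ground truth.

    Channel 0 carries the nuclear/cytoplasm stain (bright elliptical nuclei
    inside dimmer circular cytoplasm regions); channel 1 carries isotropic
    Gaussian spots confined to the cytoplasm, Gaussian read noise and an
    optional low-frequency illumination field.  Returns ``(image, truth)``
    where ``image`` has shape (2, size, size) and ``truth`` lists planted
    cells and spots with their exact rendered integrated intensities.
    """
    if size < 128:
        raise GenerationError("image size must be at least 128 px")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1337]))
    img = np.zeros((2, size, size), dtype=np.float32)

    # -- place cells by rejection sampling with a minimum-distance constraint
    margin = cytoplasm_radius + 2
    min_dist = 2 * cytoplasm_radius + 4
    centers = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n_cells} cells in a {size}px image"
            )
        cand = rng.uniform(margin, size - margin, 2)
        if all(np.hypot(*(cand - c)) >= min_dist for c in centers):
            centers.append(cand)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    truth_cells = []
    truth_spots = []
    spot_id = 0
    for cell_id, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cyto = d2 <= cytoplasm_radius ** 2
        ell_a = nucleus_radius * rng.uniform(0.85, 1.15)
        ell_b = nucleus_radius * rng.uniform(0.85, 1.15)
        nuc = ((yy - cy) / ell_a) ** 2 + ((xx - cx) / ell_b) ** 2 <= 1.0
        img[0][cyto] = np.maximum(img[0][cyto], cytoplasm_level)
        img[0][nuc] = np.maximum(img[0][nuc], nucleus_level)
        truth_cells.append({
            "cell_id": cell_id, "centroid": (float(cy), float(cx)),
            "nucleus_radii": (float(ell_a), float(ell_b)),
            "cytoplasm_radius": float(cytoplasm_radius),
        })

        # -- plant spots in the cytoplasmic ring, away from the nucleus
        r_in = max(ell_a, ell_b) + 3.0
        r_out = cytoplasm_radius - 3.0
        if r_out <= r_in and spots_per_cell > 0:
            raise GenerationError("cytoplasm too thin to hold spots")
        placed = []
        s_attempts = 0
        while len(placed) < spots_per_cell:
            s_attempts += 1
            if s_attempts > max_attempts:
                raise GenerationError(
                    f"could not place {spots_per_cell} spots in cell {cell_id}"
                )
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(r_in ** 2, r_out ** 2))
            sy, sx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            if all(np.hypot(sy - py, sx - px) >= min_spot_separation
                   for py, px in placed):
                placed.append((sy, sx))
        for sy, sx in placed:
            sigma = rng.uniform(*spot_sigma)
            half = int(np.ceil(4 * sigma))
            y0, y1 = int(sy) - half, int(sy) + half + 1
            x0, x1 = int(sx) - half, int(sx) + half + 1
            y0c, x0c = max(y0, 0), max(x0, 0)
            y1c, x1c = min(y1, size), min(x1, size)
            py, px = np.mgrid[y0c:y1c, x0c:x1c].astype(np.float64)
            kern = spot_amplitude * np.exp(
                -((py - sy) ** 2 + (px - sx) ** 2) / (2 * sigma ** 2))
            img[1, y0c:y1c, x0c:x1c] += kern.astype(np.float32)
            truth_spots.append({
                "spot_id": spot_id, "cell_id": cell_id,
                "centroid": (float(sy), float(sx)),
                "amplitude": float(spot_amplitude), "sigma": float(sigma),
                "integrated_intensity": float(kern.sum()),
            })
            spot_id += 1

    if illumination_amp > 0:
        field_ = illumination_amp * (
            0.5 + 0.5 * np.sin(2 * np.pi * xx / size)
            * np.cos(2 * np.pi * yy / size))
        img[1] += field_.astype(np.float32)
    if noise_sd > 0:
        img[0] += rng.normal(0, noise_sd, (size, size)).astype(np.float32)
        img[1] += rng.normal(0, noise_sd, (size, size)).astype(np.float32)

    truth = {"cells": truth_cells, "spots": truth_spots,
             "noise_sd": float(noise_sd), "size": int(size)}
    return img, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

_BASE_CT = {"ACTB": 18.0, "HMBS": 25.0, "TBP": 26.0}
_TARGET_BASE_CT = 24.0


def simulate_qpcr(targets, knockdown: dict, seed: int = 0,
                  noise_sd: float = 0.1, n_replicates: int = 3,
                  efficiency: float = 2.0):
    """Ct tables for control vs knockdown conditions.

    Perfect-efficiency relative quantification on the output recovers the
    planted residual fractions: a residual f shifts the target Ct by
    -log_E(f) cycles in the knockdown condition, references are unshifted.
    """
    from .qpcr import CtTable  # local import to avoid a cycle

    for gene, frac in knockdown.items():
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"knockdown fraction for {gene!r} must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x97c2]))
    rows = []
    conditions = ["control"] + [f"si{t}" for t in targets]
    genes = list(REFERENCE_GENES) + [t for t in targets
                                     if t not in REFERENCE_GENES]
    for cond in conditions:
        for gene in genes:
            base = _BASE_CT.get(gene, _TARGET_BASE_CT)
            shift = 0.0
            if cond != "control" and gene == cond[2:]:
                frac = knockdown.get(gene, 1.0)
                shift = -np.log(frac) / np.log(efficiency)
            for rep in range(1, n_replicates + 1):
                ct = base + shift
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append((cond, gene, rep, float(ct)))
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    return CtTable(df, reference_genes=set(REFERENCE_GENES),
                   efficiency=efficiency)


# ---------------------------------------------------------------------------
# AP-MS spectral counts
# ---------------------------------------------------------------------------

def simulate_apms(n_baits: int, prey_network: dict, background_freq: dict,
                  seed: int = 0, n_runs: int = 2,
                  background_count_mean: float = 3.0) -> pd.DataFrame:
    """Spectral-count runs for test baits against an unrelated-bait background.

    ``n_baits`` unrelated background baits are generated alongside the baits
    of ``prey_network`` (bait -> {prey: per-run count}).  Background preys
    appear in a ``background_freq[prey]`` fraction of all baits with
    Poisson-distributed counts; planted interactors get their stated count
    in every run of their bait only.
    """
    if n_baits < 2:
        raise ValueError("need at least 2 background baits")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA95]))
    test_baits = list(prey_network)
    background_baits = [f"BGB{i + 1:03d}" for i in range(n_baits)]
    all_baits = test_baits + background_baits

    rows = []
    for prey, freq in background_freq.items():
        m = max(1, int(round(freq * len(all_baits))))
        hit_baits = rng.choice(len(all_baits), size=min(m, len(all_baits)),
                               replace=False)
        for bi in hit_baits:
            counts = rng.poisson(background_count_mean, n_runs)
            if counts.sum() == 0:
                counts[0] = 1  # preserve the requested bait frequency
            for run in range(1, n_runs + 1):
                rows.append((all_baits[bi], prey, run, int(counts[run - 1])))
    for bait, preys in prey_network.items():
        for prey, count in preys.items():
            for run in range(1, n_runs + 1):
                rows.append((bait, prey, run, int(count)))
    df = pd.DataFrame(rows, columns=["bait", "prey", "run", "counts"])
    # merge duplicates (a planted prey may also be a background prey)
    df = (df.groupby(["bait", "prey", "run"], as_index=False)["counts"].sum()
            .sort_values(["bait", "prey", "run"], ignore_index=True))
    return df


# ---------------------------------------------------------------------------
# Expression ratios
# ---------------------------------------------------------------------------

def simulate_expression(n_genes, de_truth: dict, noise_sd: float = 0.0,
                        seed: int = 0, n_experiments: int = 3):
    """Per-experiment knockdown/control ratio tables with log-normal noise."""
    for gene, ratio in de_truth.items():
        if ratio <= 0:
            raise ValueError(f"true ratio for {gene!r} must be > 0")
    genes = _gene_names(n_genes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDE]))
    tables = []
    for exp in range(1, n_experiments + 1):
        ratios = []
        for gene in genes:
            truth = de_truth.get(gene, 1.0)
            value = truth * (np.exp(rng.normal(0.0, noise_sd))
                             if noise_sd > 0 else 1.0)
            ratios.append(float(value))
        tables.append(pd.DataFrame({"gene": genes, "ratio": ratios,
                                    "experiment": exp}))
    return tables
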
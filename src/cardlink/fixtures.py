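"""Deterministic synthetic data shaped like an AD clinical-histology study.

No real cohort data ship with this package.  The generator emulates the
*structure* of a clinical–histopathological Alzheimer's disease dataset —
patients (Az1…Azn) × hippocampal subfields (DG, CA1, CA2, CA3, SUB), with
neuronal/plaque densities, Braak stage, age and disease progression — so
every card can be exercised end to end.  It targets structure, not any real
cohort's numbers.

Key generative choices (see docs/methods.md for rationale):

* densities are lognormal with region-specific means (positive,
  right-skewed, like biological volume densities);
* the AD deficit in NeuN density is an exact subtractive shift of
  ``effect_sd`` × the theoretical pooled control SD, so the pooled
  two-group standardised effect equals ``effect_sd`` by construction;
* Braak stage is generated as the grouped stages I-II / III-IV / V-VI,
  monotone in disease progression, and Tau/Aβ densities scale up with it;
* everything is drawn from one seeded generator — the seed fully determines
  the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import Dataset, Record, Variable, infer_schema
from .images import SpatialAssociation, SpatialRegion, save_annotation

__all__ = ["FixtureConfig", "generate_clinical_dataset", "generate_section_image",
           "REGIONS", "BRAAK_STAGES"]

REGIONS = ("DG", "CA1", "CA2", "CA3", "SUB")
BRAAK_STAGES = ("I-II", "III-IV", "V-VI")

#: Control-group mean NeuN density per region (arbitrary density units);
#: ordered like REGIONS.
_NEUN_REGION_MEANS = {"DG": 110.0, "CA1": 85.0, "CA2": 95.0, "CA3": 90.0, "SUB": 75.0}
_SIGMA_LOG = 0.18  # lognormal shape: modest right skew
_BRAAK_FACTOR = {"I-II": 1.0, "III-IV": 2.5, "V-VI": 5.0}


@dataclass(frozen=True)
class FixtureConfig:
    """Study-shape knobs of the synthetic cohort.

    n_ad / n_control: patient counts (>=1 each).
    regions: hippocampal subfields; one row per patient x region.
    seed: fully determines the output.
    effect_sd: AD mean deficit in NeuN density, in units of the pooled
        control SD (1.0 = the one-SD deficit the power property assumes).
    missing_rate: fraction of histological density cells blanked at random,
        emulating incomplete records (in [0, 0.5)).
    """

    n_ad: int = 8
    n_control: int = 4
    regions: tuple = REGIONS
    seed: int = 0
    effect_sd: float = 1.0
    missing_rate: float = 0.02

    def __post_init__(self):
        if self.n_ad < 1 or self.n_control < 1:
            raise ValueError("patient counts must be >= 1")
        if not (0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5)")
        object.__setattr__(self, "regions", tuple(self.regions))


def _pooled_control_sd(regions) -> float:
    """SD of the control NeuN mixture over regions (lognormal components,
    equal weights)."""
    means = [_NEUN_REGION_MEANS.get(r, 90.0) for r in regions]
    e = float(np.mean(means))
    rel_var = math.exp(_SIGMA_LOG**2) - 1.0
    second = float(np.mean([m * m * (1.0 + rel_var) for m in means]))
    return math.sqrt(second - e * e)


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """One lognormal draw with the given arithmetic mean."""
    mu = math.log(mean) - sigma * sigma / 2.0
    return float(rng.lognormal(mu, sigma))


def _braak_for(progression: float) -> str:
    if progression < 5.0:
        return BRAAK_STAGES[0]
    if progression < 10.0:
        return BRAAK_STAGES[1]
    return BRAAK_STAGES[2]


def generate_clinical_dataset(config: FixtureConfig = FixtureConfig()) -> Dataset:
    """One row per patient × region, AD patients first (Az1…)."""
    rng = np.random.default_rng(config.seed)
    delta = config.effect_sd * _pooled_control_sd(config.regions)

    patients = []
    for i in range(config.n_ad + config.n_control):
        condition = "AD" if i < config.n_ad else "Control"
        age = round(float(np.clip(rng.normal(80.0, 7.0), 55.0, 95.0)), 1)
        if condition == "AD":
            progression = round(float(np.clip(rng.gamma(4.0, 2.0), 0.5, 20.0)), 2)
            braak = _braak_for(progression)
        else:
            progression = 0.0
            braak = BRAAK_STAGES[0]
        patients.append(
            {"label": f"Az{i + 1}", "condition": condition, "age": age,
             "progression": progression, "braak": braak}
        )

    header = [
        "Patient", "Region", "Condition", "Age at diagnosis",
        "Disease progression (years)", "Braak Scale",
        "Neuronal density per volume (NeuN)", "Neuronal density per volume (Nissl)",
        "TauPHF1 neuronal density per volume", "Aβ-ir plaques density per volume",
    ]
    density_cols = header[6:]

    rows = []
    for p in patients:
        factor = _BRAAK_FACTOR[p["braak"]]
        for region in config.regions:
            neun = _lognormal_mean(rng, _NEUN_REGION_MEANS.get(region, 90.0), _SIGMA_LOG)
            if p["condition"] == "AD":
                neun = max(neun - delta, 0.1)
            nissl = neun * 1.25 + float(rng.normal(0.0, 4.0))
            tau = _lognormal_mean(rng, 4.0 * factor, 0.35)
            abeta = _lognormal_mean(rng, 6.0 * factor, 0.35) if p["condition"] == "AD" else _lognormal_mean(
                rng, 1.0, 0.35
            )
            rows.append(
                {
                    "Patient": p["label"], "Region": region, "Condition": p["condition"],
                    "Age at diagnosis": p["age"],
                    "Disease progression (years)": p["progression"],
                    "Braak Scale": p["braak"],
                    "Neuronal density per volume (NeuN)": round(neun, 3),
                    "Neuronal density per volume (Nissl)": round(max(nissl, 0.1), 3),
                    "TauPHF1 neuronal density per volume": round(tau, 3),
                    "Aβ-ir plaques density per volume": round(abeta, 3),
                }
            )

    if config.missing_rate > 0:
        for row in rows:
            for col in density_cols:
                if rng.random() < config.missing_rate:
                    row[col] = None

    ds = Dataset(
        variables=[Variable(name=h, display_order=j) for j, h in enumerate(header)],
        rows=[Record(f"r{i}", dict(row)) for i, row in enumerate(rows)],
        source_ids=[f"synthetic:seed={config.seed}"] * len(rows),
    )
    return infer_schema(ds)


# ---------------------------------------------------------------------------
# Synthetic annotated section image


def _region_polygon(cx: float, cy: float, radius: float, n_vertices: int, rng: np.random.Generator):
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = radius * (0.75 + 0.25 * rng.random(n_vertices))
    pts = [
        (round(cx + r * math.cos(a), 2), round(cy + r * math.sin(a), 2))
        for a, r in zip(angles, radii)
    ]
    return pts


def generate_section_image(
    config: FixtureConfig,
    patient: str = "Az1",
    size: int = 256,
    out_dir: str | Path = ".",
) -> tuple[Path, Path]:
    """Write a synthetic stained-section stand-in plus its annotation JSON.

    One coloured convex-ish blob per region, centres on a ring so blobs are
    pairwise disjoint and inside the frame; the sidecar JSON annotates them
    on the variable "Region".  The annotation is byte-identical across runs
    with the same seed.  Returns (image path, annotation path).
    """
    if size < 64:
        raise ValueError("image size must be >= 64 px")
    from PIL import Image, ImageDraw

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # derive a per-patient stream from a stable (unsalted) label key
    key = sum((i + 1) * ord(c) for i, c in enumerate(patient)) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, key]))

    n = len(config.regions)
    centre = size / 2.0
    ring = size * 0.30
    radius = min(size * 0.12, ring * math.sin(math.pi / max(n, 2)) * 0.9)
    regions = []
    for i, name in enumerate(config.regions):
        a = 2.0 * math.pi * i / n
        cx, cy = centre + ring * math.cos(a), centre + ring * math.sin(a)
        regions.append(SpatialRegion(name, _region_polygon(cx, cy, radius, 7, rng)))
    assoc = SpatialAssociation("Region", regions)

    img = Image.new("RGB", (size, size), (235, 228, 215))
    draw = ImageDraw.Draw(img)
    palette = [(178, 102, 96), (121, 140, 178), (140, 171, 120), (188, 158, 104), (150, 120, 160)]
    for i, region in enumerate(assoc.regions):
        draw.polygon([(x, y) for x, y in region.polygon], fill=palette[i % len(palette)], outline=(60, 50, 45))

    img_path = out_dir / f"section_{patient}.png"
    ann_path = out_dir / f"section_{patient}.annotation.json"
    img.save(img_path)
    save_annotation(assoc, ann_path)
    return img_path, ann_path
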
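"""Synthetic herbarium datasets with known ground truth.

Every downstream stage — label-text classification, circular model
selection, climate regionalization and calendar assembly — is exercised
against data generated here, where the true flowering status, the true
circular model of each species and the true climate template of each grid
cell are all recorded.  The generator emulates the statistical structure
of a curated neotropical occurrence table: multilingual field notes,
month-precision dates, per-species record counts from a handful to
hundreds, and gridded monthly climate with planted seasonality.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _lexicon
from .circstats import MODEL_SPECS, angle_to_month_day

__all__ = [
    "RegionTemplate",
    "SyntheticConfig",
    "default_region_templates",
    "sample_angles",
    "angles_to_dates",
    "make_label_text",
    "make_dataset",
    "make_synonym_table",
    "make_climate_grid",
]


@dataclass(frozen=True)
class RegionTemplate:
    """A planted climate archetype: 12 monthly precip/temp values plus a
    geographic extent in which its grid cells and records are placed."""

    name: str
    precip: tuple[float, ...]  # mm per month
    temp: tuple[float, ...]  # degrees C monthly mean
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    n_cells: int = 60
    jitter: float = 0.05  # relative noise scale applied per cell

    def __post_init__(self) -> None:
        if len(self.precip) != 12 or len(self.temp) != 12:
            raise ValueError(f"template {self.name!r} needs 12 monthly values")
        if any(p < 0 for p in self.precip):
            raise ValueError("precipitation must be non-negative")


def default_region_templates() -> list[RegionTemplate]:
    """Six seasonality archetypes spanning the neotropical realm.

    Loosely: equatorial montane forest, a dry Caribbean belt, the Cerrado
    with its winter drought, the ever-wet Chocó–Napo lowlands, the
    seasonal Amazon, and cold high-elevation páramo/puna.
    """
    return [
        RegionTemplate(
            "montane-equatorial",
            precip=(180, 170, 200, 230, 200, 130, 90, 80, 120, 190, 210, 190),
            temp=(19, 19, 19.5, 19.5, 19, 18.5, 18, 18, 18.5, 19, 19, 19),
            lat_range=(-5.0, 5.0), lon_range=(-79.0, -75.2),
        ),
        RegionTemplate(
            "dry-caribbean",
            precip=(20, 15, 20, 60, 140, 160, 130, 170, 190, 180, 90, 30),
            temp=(26, 26.5, 27, 27.5, 27.5, 27.5, 27.5, 27.5, 27, 27, 26.5, 26),
            lat_range=(8.0, 15.0), lon_range=(-85.0, -70.0),
        ),
        RegionTemplate(
            "cerrado",
            precip=(250, 210, 190, 110, 40, 15, 10, 15, 55, 140, 200, 250),
            temp=(23, 23, 23, 22.5, 21, 20, 20, 21.5, 23.5, 24, 23.5, 23),
            lat_range=(-23.0, -13.0), lon_range=(-55.0, -45.0),
        ),
        RegionTemplate(
            "choco-napo",
            precip=(310, 290, 320, 340, 330, 300, 280, 270, 290, 320, 330, 320),
            temp=(25.5, 25.5, 26, 26, 25.5, 25, 25, 25, 25, 25.5, 25.5, 25.5),
            lat_range=(-3.0, 6.0), lon_range=(-75.0, -70.0),
        ),
        RegionTemplate(
            "amazon-seasonal",
            precip=(290, 300, 310, 250, 160, 90, 60, 70, 110, 170, 220, 270),
            temp=(26, 26, 26, 26, 25.5, 25, 25, 25.5, 26.5, 26.5, 26.5, 26),
            lat_range=(-12.0, -3.0), lon_range=(-65.0, -50.0),
        ),
        RegionTemplate(
            "paramo-puna",
            precip=(110, 120, 130, 120, 80, 50, 40, 45, 70, 110, 110, 110),
            temp=(8, 8, 8.5, 8.5, 8, 7.5, 7, 7, 7.5, 8, 8.5, 8.5),
            lat_range=(-16.0, -6.0), lon_range=(-76.0, -69.8),
        ),
    ]


_GENERA = (
    "Miconia", "Ocotea", "Inga", "Palicourea", "Guarea", "Ficus",
    "Casearia", "Myrcia", "Nectandra", "Cecropia", "Piper", "Solanum",
)

# Auto-assigned species models cycle through the three pattern families
# with realistic parameters; peaks are drawn per species.
_FAMILY_CYCLE = ("unimodal", "bimodal", "uniform")


@dataclass
class SyntheticConfig:
    """Everything the generator needs; defaults give a mid-sized study."""

    seed: int = 0
    n_species: int = 30
    records_per_species: int | Sequence[int] | Mapping[str, int] = 120
    flowering_fraction: float = 0.55
    label_noise_rate: float = 0.05
    missing_day_fraction: float = 0.10
    synonym_fraction: float = 0.10
    species_models: dict[str, tuple[str, dict[str, float]]] | None = None
    year_range: tuple[int, int] = (1980, 2020)
    region_templates: list[RegionTemplate] = field(default_factory=default_region_templates)

    def __post_init__(self) -> None:
        for name in ("flowering_fraction", "label_noise_rate",
                     "missing_day_fraction", "synonym_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ValueError(f"invalid year_range {self.year_range}")
        if not self.region_templates:
            raise ValueError("need at least one region template")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.species_models:
            for sp, (mid, params) in self.species_models.items():
                _validate_model_params(mid, params)


def _validate_model_params(model_id: str, params: Mapping[str, float]) -> None:
    if model_id not in MODEL_SPECS:
        raise ValueError(f"unknown model id {model_id!r}")
    for k in ("k1", "k2"):
        if k in params and params[k] < 0:
            raise ValueError(f"{k} must be >= 0")
    if "lam" in params and not 0.5 <= params["lam"] <= 1.0:
        raise ValueError("lam must lie in [0.5, 1]")


def sample_angles(
    model_id: str, params: Mapping[str, float], n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` i.i.d. angles (degrees) from one of the ten circular models."""
    _validate_model_params(model_id, params)
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = MODEL_SPECS[model_id]
    rng = np.random.default_rng(seed)
    if spec.id == "M1":
        return rng.uniform(0.0, 360.0, n)

    mu1 = float(params.get("mu1", 0.0))
    k1 = float(params.get("k1", 1.0))
    lam = 1.0 if spec.second == "none" else (
        spec.lam_fixed if spec.lam_fixed is not None else float(params.get("lam", 0.5))
    )
    first = rng.random(n) < lam
    out = np.empty(n)
    out[first] = _vm_draw(rng, mu1, k1, int(first.sum()))
    n2 = int((~first).sum())
    if spec.second == "uniform":
        out[~first] = rng.uniform(0.0, 360.0, n2)
    elif spec.second == "vm":
        mu2 = (mu1 + 180.0) % 360.0 if spec.axial else float(params.get("mu2", (mu1 + 180) % 360))
        k2 = k1 if spec.homogeneous else float(params.get("k2", k1))
        out[~first] = _vm_draw(rng, mu2, k2, n2)
    return out % 360.0


def _vm_draw(rng: np.random.Generator, mu_deg: float, k: float, n: int) -> np.ndarray:
    if k == 0:
        return rng.uniform(0.0, 360.0, n)
    return np.degrees(rng.vonmises(np.radians(mu_deg), k, n)) % 360.0


def angles_to_dates(
    angles: Sequence[float], year_range: tuple[int, int], seed: int
) -> list[_dt.date]:
    """Map angles back to calendar dates, with years drawn uniformly.

    Inverse of the 30°-per-month mapping: each output date re-maps to its
    input angle within one day's angular width.  29 February is never
    produced (the angular scale folds it onto the 28th).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    if np.any((angles < 0) | (angles >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    y0, y1 = year_range
    if y0 > y1:
        raise ValueError(f"invalid year_range {year_range}")
    rng = np.random.default_rng(seed)
    years = rng.integers(y0, y1 + 1, size=angles.size)
    out = []
    for a, y in zip(angles, years):
        month, day = angle_to_month_day(float(a))
        out.append(_dt.date(int(y), month, day))
    return out


def make_label_text(
    flowering: bool,
    noise_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    flowering_pool: Sequence[str] = _lexicon.FLOWERING_PHRASES,
    non_flowering_pool: Sequence[str] = _lexicon.NON_FLOWERING_PHRASES,
    neutral_pool: Sequence[str] = _lexicon.NEUTRAL_PHRASES,
) -> str:
    """Compose a field-note string for a record of known flowering status.

    With probability ``1 − noise_rate`` the text carries a phrase from the
    truth-consistent pool (and none from the opposite pool); otherwise the
    phrase comes from the opposite pool — an intentionally contradictory
    label emulating ambiguous field notes.
    """
    if not flowering_pool or not non_flowering_pool:
        raise ValueError("phrase pools must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    truthful = rng.random() >= noise_rate
    use_flowering = flowering if truthful else not flowering
    pool = flowering_pool if use_flowering else non_flowering_pool
    parts = [str(rng.choice(list(neutral_pool))), str(rng.choice(list(pool)))]
    if rng.random() < 0.5:
        parts.append(str(rng.choice(list(neutral_pool))))
    return "; ".join(parts)


def _species_names(n: int) -> list[str]:
    return [f"{_GENERA[i % len(_GENERA)]} simulata{i:03d}" for i in range(n)]


def _auto_model(i: int, rng: np.random.Generator) -> tuple[str, dict[str, float]]:
    fam = _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)]
    if fam == "uniform":
        return "M1", {}
    mu1 = float(rng.uniform(0, 360))
    k1 = float(rng.uniform(2.0, 4.0))
    if fam == "unimodal":
        return "M2A", {"mu1": mu1, "k1": k1}
    sep = float(rng.uniform(150.0, 210.0))
    return "M5B", {
        "mu1": mu1, "k1": k1,
        "mu2": (mu1 + sep) % 360.0, "k2": float(rng.uniform(2.0, 4.0)),
        "lam": float(rng.uniform(0.5, 0.65)),
    }


def _records_count(config: SyntheticConfig, i: int, name: str) -> int:
    spec = config.records_per_species
    if isinstance(spec, Mapping):
        return int(spec[name])
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    return int(spec[i % len(spec)])


def make_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a Darwin-Core-style specimen table plus its truth table.

    The specimen table carries exactly what a curated occurrence download
    would: name (sometimes a synonym), eventDate (sometimes month
    precision), coordinates inside the species' home region, field notes
    and a catalogue number.  The truth table records each record's true
    flowering flag and angle, and each species' true circular model.
    """
    rng = np.random.default_rng(config.seed)
    names = _species_names(config.n_species)
    templates = config.region_templates
    rows, truth_rows = [], []
    rec_idx = 0
    for i, name in enumerate(names):
        if config.species_models and name in config.species_models:
            model_id, params = config.species_models[name]
        else:
            model_id, params = _auto_model(i, rng)
        tpl = templates[i % len(templates)]
        n_rec = _records_count(config, i, name)
        flowering = rng.random(n_rec) < config.flowering_fraction
        n_fl = int(flowering.sum())
        angles = np.empty(n_rec)
        if n_fl:
            angles[flowering] = sample_angles(
                model_id, params, n_fl, seed=int(rng.integers(2**31)))
        angles[~flowering] = rng.uniform(0, 360, n_rec - n_fl)
        dates = angles_to_dates(angles, config.year_range,
                                seed=int(rng.integers(2**31)))
        lats = rng.uniform(*tpl.lat_range, n_rec)
        lons = rng.uniform(*tpl.lon_range, n_rec)
        for j in range(n_rec):
            catalog = f"SYN-{rec_idx:06d}"
            rec_idx += 1
            d = dates[j]
            missing_day = rng.random() < config.missing_day_fraction
            event = f"{d.year:04d}-{d.month:02d}" if missing_day else d.isoformat()
            use_syn = rng.random() < config.synonym_fraction
            genus, epithet = name.split(" ", 1)
            written = f"{genus}opsis {epithet}" if use_syn else name
            rows.append({
                "scientificName": written,
                "eventDate": event,
                "decimalLatitude": round(float(lats[j]), 5),
                "decimalLongitude": round(float(lons[j]), 5),
                "fieldNotes": make_label_text(
                    bool(flowering[j]), config.label_noise_rate, rng=rng),
                "catalogNumber": catalog,
            })
            truth_rows.append({
                "catalogNumber": catalog,
                "species": name,
                "flowering": bool(flowering[j]),
                "angle": float(angles[j]),
                "month": d.month,
                "day": None if missing_day else d.day,
                "model": model_id,
                "region_template": tpl.name,
                **{f"true_{k}": v for k, v in params.items()},
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def make_synonym_table(config: SyntheticConfig) -> pd.DataFrame:
    """Synonym → accepted-name table covering every generated name form."""
    rows = []
    for name in _species_names(config.n_species):
        genus, epithet = name.split(" ", 1)
        rows.append({"synonym": name, "accepted": name})
        rows.append({"synonym": f"{genus}opsis {epithet}", "accepted": name})
    return pd.DataFrame(rows)


def make_climate_grid(config: SyntheticConfig) -> pd.DataFrame:
    """Gridded monthly climate: template values plus seeded jitter per cell."""
    templates = config.region_templates
    if len(templates) < 1:
        raise ValueError("need at least one region template")
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    cell_id = 0
    for tpl in templates:
        p = np.asarray(tpl.precip, float)
        t = np.asarray(tpl.temp, float)
        t_amp = max(t.max() - t.min(), 1.0)
        for _ in range(tpl.n_cells):
            pj = np.maximum(0.0, p * (1.0 + tpl.jitter * rng.standard_normal(12)))
            tj = t + tpl.jitter * t_amp * rng.standard_normal(12)
            row = {
                "cell_id": cell_id,
                "latitude": round(float(rng.uniform(*tpl.lat_range)), 5),
                "longitude": round(float(rng.uniform(*tpl.lon_range)), 5),
                "template": tpl.name,
            }
            row.update({f"prec_{m:02d}": round(float(pj[m - 1]), 3) for m in range(1, 13)})
            row.update({f"temp_{m:02d}": round(float(tj[m - 1]), 3) for m in range(1, 13)})
            rows.append(row)
            cell_id += 1
    return pd.DataFrame(rows)
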
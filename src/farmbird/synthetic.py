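"""Synthetic agricultural landscape, bird community and survey generator.

Emulates the statistical structure of a national breeding-bird monitoring
scheme run over small agricultural regions (SARs): regions with areas,
agroecosystem types and nine-crop compositions; species with log-linear
abundance coefficients and Gaussian random-intercept SDs; and two-visit
point-count tables whose regional totals follow a Poisson log-normal model

    Abundance ~ Poisson(exp(alpha + b1*C + b2*F + b3*P + sum_k bk*X_k
                            + u_region + v_year + eps_obs))

with C climatic suitability, F farmland-habitat proportion, P survey effort
(number of farmland count points) and X_k the crop shares.

Everything is driven by an explicit seed; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "CROPS",
    "AGROECOSYSTEMS",
    "SUBHABITATS",
    "Region",
    "SpeciesProfile",
    "generate_regions",
    "generate_species",
    "generate_grid",
    "generate_overlaps",
    "generate_model_projections",
    "simulate_regional_counts",
    "generate_surveys",
    "regions_to_frame",
    "species_to_frame",
]

#: The nine crop / grassland categories whose UAA shares are modelled.
CROPS = (
    "permanent_grassland",
    "temporary_grassland",
    "cereals",
    "grain_maize",
    "rapeseed",
    "sunflower",
    "corn_fodder",
    "proteaginous",
    "forage_crops",
)

AGROECOSYSTEMS = ("arable", "livestock", "mixed")

#: Farmland sub-habitats ordered by grassland affinity (weights 4, 3, 2, 1).
SUBHABITATS = ("unimproved_grassland", "improved_grassland", "mixed", "cropland")

# Dirichlet concentrations per agroecosystem: arable regions are
# cereal/oilseed-heavy, livestock regions grassland-heavy, mixed in between.
_CROP_CONCENTRATION = {
    "arable": np.array([0.8, 1.2, 16.0, 5.0, 5.0, 3.0, 1.0, 2.0, 1.0]),
    "livestock": np.array([16.0, 6.0, 3.0, 0.8, 0.5, 0.3, 3.0, 0.5, 4.0]),
    "mixed": np.array([7.0, 4.0, 8.0, 3.0, 2.0, 1.5, 3.0, 1.5, 2.0]),
}

_AREA_RANGE_KM2 = (11.0, 4413.0)


@dataclass
class Region:
    """One small agricultural region (SAR)."""

    region_id: str
    area: float  # km^2
    agroecosystem: str
    crop_shares: np.ndarray  # 9 UAA proportions, sum to 1
    farmland_prop_current: float | None = None
    farmland_prop_future: float | None = None
    n_points: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.area <= 0:
            raise ValueError(f"{self.region_id}: area must be > 0")
        s = np.asarray(self.crop_shares, dtype=float)
        if s.shape != (len(CROPS),):
            raise ValueError(f"{self.region_id}: expected {len(CROPS)} crop shares")
        if (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise ValueError(f"{self.region_id}: crop shares must lie in [0, 1]")
        if abs(s.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.region_id}: crop shares sum to {s.sum()!r}, not 1")
        for prop in (self.farmland_prop_current, self.farmland_prop_future):
            if prop is not None and not (0.0 <= prop <= 1.0):
                raise ValueError(f"{self.region_id}: farmland proportion outside [0, 1]")
        for year, n in self.n_points.items():
            if int(n) != n or n < 0:
                raise ValueError(f"{self.region_id}: n_points[{year}] must be a non-negative integer")


@dataclass
class SpeciesProfile:
    """A species with its true abundance-model coefficients.

    ``beta_crops`` holds the nine crop coefficients; together with the
    climate, farmland and effort coefficients the non-intercept coefficient
    vector has length 12.
    """

    species_id: str
    specialization: str  # "farmland" | "generalist"
    migrant_second_visit_only: bool
    alpha: float
    beta_climate: float
    beta_farmland: float
    beta_effort: float
    beta_crops: np.ndarray
    random_sd_region: float
    random_sd_year: float
    random_sd_obs: float
    subhabitat_abundance: np.ndarray | None = None  # 4 values, see SUBHABITATS

    @property
    def coefficients(self) -> np.ndarray:
        """Non-intercept coefficient vector (length 12)."""
        return np.concatenate(
            [[self.beta_climate, self.beta_farmland, self.beta_effort], self.beta_crops]
        )

    def validate(self) -> None:
        if self.specialization not in ("farmland", "generalist"):
            raise ValueError(f"{self.species_id}: unknown specialization {self.specialization!r}")
        if len(np.asarray(self.beta_crops)) != len(CROPS):
            raise ValueError(f"{self.species_id}: expected {len(CROPS)} crop coefficients")
        for sd in (self.random_sd_region, self.random_sd_year, self.random_sd_obs):
            if sd < 0:
                raise ValueError(f"{self.species_id}: random-effect SDs must be >= 0")


def generate_regions(
    n_regions: int,
    seed: int,
    agro_probs: Mapping[str, float] | None = None,
) -> list[Region]:
    """Draw ``n_regions`` synthetic agricultural regions.

    Areas are log-uniform on [11, 4413] km^2 (matching the span of French
    SARs); agroecosystem labels come from ``agro_probs`` (default
    arable 0.4 / livestock 0.3 / mixed 0.3, echoing the roughly 2:1
    cropland:grassland split of French UAA); crop shares are Dirichlet draws
    conditioned on the agroecosystem.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if agro_probs is None:
        agro_probs = {"arable": 0.4, "livestock": 0.3, "mixed": 0.3}
    labels = list(agro_probs)
    probs = np.array([agro_probs[k] for k in labels], dtype=float)
    probs = probs / probs.sum()

    rng = substream(seed, "regions")
    lo, hi = np.log(_AREA_RANGE_KM2[0]), np.log(_AREA_RANGE_KM2[1])
    areas = np.exp(rng.uniform(lo, hi, size=n_regions))
    agro = rng.choice(labels, size=n_regions, p=probs)

    regions = []
    for i in range(n_regions):
        shares = rng.dirichlet(_CROP_CONCENTRATION[agro[i]])
        shares = shares / shares.sum()  # guard against float drift
        r = Region(
            region_id=f"R{i:04d}",
            area=float(areas[i]),
            agroecosystem=str(agro[i]),
            crop_shares=shares,
        )
        r.validate()
        regions.append(r)
    return regions


def generate_species(
    n_farmland: int,
    n_generalist: int,
    seed: int,
    n_migrants: int | None = None,
    random_sd_region: float = 0.3,
    random_sd_year: float = 0.1,
    random_sd_obs: float = 0.2,
) -> list[SpeciesProfile]:
    """Draw a synthetic bird community.

    Farmland specialists get strong crop coefficients (their abundance tracks
    farmland composition) and spiky sub-habitat profiles; generalists get
    near-zero crop coefficients and even profiles. ``n_migrants`` farmland
    species (default ``min(3, n_farmland)``, mirroring the three late-spring
    migrants of the study community) are flagged so only their second survey
    visit is informative.
    """
    if n_farmland < 0 or n_generalist < 0:
        raise ValueError("species counts must be >= 0")
    if n_farmland + n_generalist == 0:
        raise ValueError("at least one species is required")
    if n_migrants is None:
        n_migrants = min(3, n_farmland)
    if n_migrants > n_farmland:
        raise ValueError("n_migrants cannot exceed n_farmland")

    rng = substream(seed, "species")
    out: list[SpeciesProfile] = []
    migrant_ids = set(rng.choice(n_farmland, size=n_migrants, replace=False)) if n_farmland else set()
    specs = ["farmland"] * n_farmland + ["generalist"] * n_generalist
    for i, spec in enumerate(specs):
        if spec == "farmland":
            beta_crops = rng.normal(0.0, 0.6, size=len(CROPS))
            subhab = rng.dirichlet([0.7, 0.7, 0.7, 0.7])
        else:
            beta_crops = rng.normal(0.0, 0.05, size=len(CROPS))
            subhab = rng.dirichlet([3.0, 3.0, 3.0, 3.0])
        p = SpeciesProfile(
            species_id=f"S{i:03d}",
            specialization=spec,
            migrant_second_visit_only=(spec == "farmland" and i in migrant_ids),
            alpha=float(rng.normal(np.log(5.0), 0.3)),
            beta_climate=float(rng.normal(0.8, 0.2)),
            beta_farmland=float(rng.normal(0.5, 0.15)),
            beta_effort=float(rng.normal(0.03, 0.01)),
            beta_crops=beta_crops,
            random_sd_region=random_sd_region,
            random_sd_year=random_sd_year,
            random_sd_obs=random_sd_obs,
            subhabitat_abundance=subhab,
        )
        p.validate()
        out.append(p)
    return out


def generate_grid(n_cells: int, seed: int, species_ids: Sequence[str] = ()) -> pd.DataFrame:
    """Generate a 0.5-degree-style grid table.

    Returns one row per cell with three land-cover class fractions (pasture,
    cultivated, mosaic) for current and future periods, plus per-species
    suitability columns ``suit_current_<sp>`` / ``suit_future_<sp>`` in [0, 1].
    Future suitability drifts downward on average (range retraction under
    warming) with cell-level noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = substream(seed, "grid")
    rows: dict[str, np.ndarray] = {"cell_id": np.array([f"C{i:04d}" for i in range(n_cells)])}
    for period in ("current", "future"):
        frac = rng.dirichlet([2.0, 3.0, 1.5, 2.5], size=n_cells)  # 4th = non-farmland
        rows[f"pasture_{period}"] = frac[:, 0]
        rows[f"cultivated_{period}"] = frac[:, 1]
        rows[f"mosaic_{period}"] = frac[:, 2]
    for sp in species_ids:
        cur = rng.beta(2.0, 2.0, size=n_cells)
        drift = rng.normal(-0.08, 0.10, size=n_cells)
        rows[f"suit_current_{sp}"] = cur
        rows[f"suit_future_{sp}"] = np.clip(cur + drift, 0.0, 1.0)
    return pd.DataFrame(rows)


def generate_overlaps(regions: Sequence[Region], n_cells: int, seed: int) -> pd.DataFrame:
    """Fabricate region-normalized grid overlaps.

    Each region intersects 1-4 grid cells; the fractions of the region's area
    in each cell are Dirichlet draws summing to 1, mirroring how suitability
    is averaged per SAR weighted by the proportion of the SAR in each cell.
    Returns a DataFrame with columns cell_id, region_id, fraction.
    """
    rng = substream(seed, "overlaps")
    recs = []
    for r in regions:
        k = int(rng.integers(1, min(4, n_cells) + 1))
        cells = rng.choice(n_cells, size=k, replace=False)
        fracs = rng.dirichlet(np.full(k, 2.0))
        for c, f in zip(cells, fracs):
            recs.append((f"C{int(c):04d}", r.region_id, float(f)))
    return pd.DataFrame(recs, columns=["cell_id", "region_id", "fraction"])


def generate_model_projections(
    grid: pd.DataFrame,
    species_id: str,
    n_models: int,
    seed: int,
    noise_sd: float = 0.08,
) -> pd.DataFrame:
    """Per-SDM suitability layers around the grid's latent suitability.

    Stand-in for the projections of an ensemble of distribution models (the
    models themselves are out of scope): each synthetic "model" perturbs the
    latent suitability with its own bias and noise. Returns long-format rows
    (model_id, cell_id, period, value).
    """
    rng = substream(seed, f"projections:{species_id}")
    recs = []
    for m in range(n_models):
        bias = rng.normal(0.0, 0.04)
        for period in ("current", "future"):
            base = grid[f"suit_{period}_{species_id}"].to_numpy()
            vals = np.clip(base + bias + rng.normal(0.0, noise_sd, size=len(base)), 0.0, 1.0)
            for cid, v in zip(grid["cell_id"], vals):
                recs.append((f"M{m}", cid, period, float(v)))
    return pd.DataFrame(recs, columns=["model_id", "cell_id", "period", "value"])


def _linear_predictor(
    profile: SpeciesProfile,
    suitability: float,
    farmland_prop: float,
    n_points: int,
    crop_shares: np.ndarray,
) -> float:
    return float(
        profile.alpha
        + profile.beta_climate * suitability
        + profile.beta_farmland * farmland_prop
        + profile.beta_effort * n_points
        + crop_shares @ profile.beta_crops
    )


def simulate_regional_counts(
    regions: Sequence[Region],
    profile: SpeciesProfile,
    years: Sequence[int],
    seed: int,
    suitability: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate region x year abundance directly from the Poisson log-normal model.

    The lighter sibling of :func:`generate_surveys`: no point-level detail,
    one Poisson draw per region x year around
    ``exp(eta + u_region + v_year + eps_obs)``. ``suitability`` maps
    region_id -> climatic suitability; defaults to Beta(2, 2) draws.
    Returns columns region_id, year, abundance, n_points, suitability,
    farmland_prop and the nine crop-share columns.
    """
    if not regions or not years:
        raise ValueError("regions and years must be non-empty")
    rng = substream(seed, f"counts:{profile.species_id}")
    if suitability is None:
        suitability = {r.region_id: float(rng.beta(2.0, 2.0)) for r in regions}
    u = {r.region_id: rng.normal(0.0, profile.random_sd_region) for r in regions}
    v = {y: rng.normal(0.0, profile.random_sd_year) for y in years}

    recs = []
    for r in regions:
        fp = r.farmland_prop_current if r.farmland_prop_current is not None else 0.5
        for y in years:
            npts = r.n_points.get(y, 10)
            eta = _linear_predictor(profile, suitability[r.region_id], fp, npts, np.asarray(r.crop_shares))
            eps = rng.normal(0.0, profile.random_sd_obs)
            mu = np.exp(min(eta + u[r.region_id] + v[y] + eps, 30.0))
            recs.append(
                (r.region_id, y, int(rng.poisson(mu)), npts, suitability[r.region_id], fp)
                + tuple(np.asarray(r.crop_shares))
            )
    cols = ["region_id", "year", "abundance", "n_points", "suitability", "farmland_prop"]
    return pd.DataFrame(recs, columns=cols + list(CROPS))


def generate_surveys(
    regions: Sequence[Region],
    species: Sequence[SpeciesProfile],
    years: Sequence[int],
    seed: int,
    suitability: Mapping[tuple[str, str], float] | None = None,
    low_farmland_square_frac: float = 0.1,
    stray_rate: float = 0.1,
) -> pd.DataFrame:
    """Simulate two-visit point-count tables.

    Squares of 10 points are laid out per region (1-3 squares); a fraction
    ``low_farmland_square_frac`` have fewer than 5 farmland points and are
    therefore destined to be dropped by the survey filter. For every
    species x region x year the regional total is a Poisson draw around the
    log-normal mean and is partitioned uniformly across the farmland points
    of retained squares. Visit 2 carries a point's full annual count and
    visit 1 a binomial thinning of it, so the max-of-two-visits rule (and the
    second-visit rule for migrants) recovers the latent count exactly and the
    regional abundance keeps the generative Poisson log-normal distribution.
    Points outside the retained farmland set receive small independent
    Poisson(``stray_rate``) counts.

    Returns columns species_id, region_id, year, square_id, point_id,
    visit1_count, visit2_count, point_is_farmland. Also fills each region's
    ``n_points`` map (farmland points in retained squares, per year).
    """
    if not regions or not species:
        raise ValueError("regions and species must be non-empty")
    if not years:
        raise ValueError("years must be non-empty")
    rng = substream(seed, "surveys")
    if suitability is None:
        suitability = {
            (p.species_id, r.region_id): float(rng.beta(2.0, 2.0)) for p in species for r in regions
        }

    # fixed square/point layout per region (observers revisit the same points)
    layout = {}
    for r in regions:
        squares = []
        for sq in range(int(rng.integers(1, 4))):
            if rng.random() < low_farmland_square_frac:
                n_farm = int(rng.integers(0, 5))
            else:
                n_farm = int(rng.integers(5, 11))
            squares.append((f"{r.region_id}-sq{sq}", n_farm))
        layout[r.region_id] = squares
        retained = sum(nf for _, nf in squares if nf >= 5)
        for y in years:
            r.n_points[y] = retained

    recs = []
    for p in species:
        u = {r.region_id: rng.normal(0.0, p.random_sd_region) for r in regions}
        v = {y: rng.normal(0.0, p.random_sd_year) for y in years}
        for r in regions:
            fp = r.farmland_prop_current if r.farmland_prop_current is not None else 0.5
            shares = np.asarray(r.crop_shares)
            farm_points = [
                (sq_id, k)
                for sq_id, n_farm in layout[r.region_id]
                if n_farm >= 5
                for k in range(n_farm)
            ]
            for y in years:
                eta = _linear_predictor(p, suitability[(p.species_id, r.region_id)], fp, r.n_points[y], shares)
                eps = rng.normal(0.0, p.random_sd_obs)
                mu = np.exp(min(eta + u[r.region_id] + v[y] + eps, 30.0))
                total = int(rng.poisson(mu)) if farm_points else 0
                if farm_points:
                    alloc = rng.multinomial(total, np.full(len(farm_points), 1.0 / len(farm_points)))
                else:
                    alloc = []
                for (sq_id, k), cnt in zip(farm_points, alloc):
                    v1 = int(rng.binomial(cnt, 0.7))
                    recs.append((p.species_id, r.region_id, y, sq_id, f"{sq_id}-pt{k}", v1, int(cnt), True))
                # points that the filter will discard: non-farmland points and
                # whole squares with < 5 farmland points
                for sq_id, n_farm in layout[r.region_id]:
                    pts = []
                    if n_farm < 5:
                        pts += [(f"{sq_id}-pt{k}", k < n_farm) for k in range(10)]
                    else:
                        pts += [(f"{sq_id}-pt{k}", False) for k in range(n_farm, 10)]
                    for pid, is_farm in pts:
                        recs.append(
                            (p.species_id, r.region_id, y, sq_id, pid,
                             int(rng.poisson(stray_rate)), int(rng.poisson(stray_rate)), bool(is_farm))
                        )
    return pd.DataFrame(
        recs,
        columns=[
            "species_id", "region_id", "year", "square_id", "point_id",
            "visit1_count", "visit2_count", "point_is_farmland",
        ],
    )


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Flatten Region objects to the regions.csv schema."""
    recs = []
    for r in regions:
        rec = {
            "region_id": r.region_id,
            "area": r.area,
            "agroecosystem": r.agroecosystem,
            "farmland_prop_current": r.farmland_prop_current,
            "farmland_prop_future": r.farmland_prop_future,
        }
        rec.update({c: float(s) for c, s in zip(CROPS, r.crop_shares)})
        recs.append(rec)
    return pd.DataFrame(recs)


def species_to_frame(species: Sequence[SpeciesProfile]) -> pd.DataFrame:
    """Flatten SpeciesProfile objects to the species.csv schema."""
    recs = []
    for p in species:
        rec = {
            "species_id": p.species_id,
            "specialization": p.specialization,
            "migrant_second_visit_only": p.migrant_second_visit_only,
            "alpha": p.alpha,
            "beta_climate": p.beta_climate,
            "beta_farmland": p.beta_farmland,
            "beta_effort": p.beta_effort,
            "random_sd_region": p.random_sd_region,
            "random_sd_year": p.random_sd_year,
            "random_sd_obs": p.random_sd_obs,
        }
        rec.update({f"beta_{c}": float(b) for c, b in zip(CROPS, p.beta_crops)})
        if p.subhabitat_abundance is not None:
            rec.update({f"abund_{h}": float(a) for h, a in zip(SUBHABITATS, p.subhabitat_abundance)})
        recs.append(rec)
    return pd.DataFrame(recs)
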
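"""Sediment-trap strontium flux analysis.

Acantharian cysts are celestite (SrSO₄), so a pulse of sinking cysts shows
up as excess dissolved Sr in a trap bottle over the seawater background
(~8 µg mL⁻¹ of preservative).  Per trap, the background is the mean of all
bottles under a 9 µg mL⁻¹ cutoff; a bottle is significantly elevated when
its concentration exceeds mean + 2·SD (strict).  For significant bottles:

    sr_flux [mg m⁻² d⁻¹] = (conc − background) · volume / 1000
                           / (collection_area · duration)

with uncertainty from 1% analytical error on the measured concentration
and the background SD, combined in quadrature and scaled like the flux.
Carbon flux follows from a cellular C:Sr mass ratio (0.120 ± 0.022 mg/mg),
with relative uncertainties combined in quadrature, and can be expressed
as a percentage of the total POC flux.  A carbonate sanity bound converts
a measured Ca elevation into the maximum Sr it could contribute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_CUTOFF = 9.0  # µg Sr mL⁻¹
DEFAULT_COLLECTION_AREA = 0.66  # m²


@dataclass(frozen=True)
class TrapBottle:
    """One sequential collection bottle."""

    trap_id: str
    bottle_id: str
    duration_days: float
    volume_ml: float
    sr_conc: float  # µg mL⁻¹
    ca_conc: float | None = None  # µg mL⁻¹, optional

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError(f"bottle {self.bottle_id!r}: duration must be > 0")
        if self.volume_ml <= 0:
            raise ValueError(f"bottle {self.bottle_id!r}: volume must be > 0")
        if self.sr_conc < 0:
            raise ValueError(f"bottle {self.bottle_id!r}: Sr concentration < 0")


@dataclass
class TrapSeries:
    """An ordered bottle series from one trap deployment."""

    trap_id: str
    bottles: list[TrapBottle]
    collection_area: float = DEFAULT_COLLECTION_AREA

    def __post_init__(self) -> None:
        if self.collection_area <= 0:
            raise ValueError("collection area must be > 0")
        if len(self.bottles) < 3:
            raise ValueError(
                f"trap {self.trap_id!r}: need >= 3 bottles for background "
                f"estimation, got {len(self.bottles)}"
            )


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-trap background Sr level from sub-cutoff bottles (sample SD)."""

    mean: float
    sd: float
    n_bottles_used: int
    cutoff: float = DEFAULT_BACKGROUND_CUTOFF


@dataclass(frozen=True)
class CSrRatio:
    """Cellular organic carbon per unit strontium, mg C per mg Sr."""

    value: float = 0.120
    sd: float = 0.022

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("C:Sr ratio must be positive")
        if self.sd < 0:
            raise ValueError("C:Sr ratio sd must be >= 0")


@dataclass(frozen=True)
class FluxResult:
    """Per-bottle significance flag and derived fluxes (None if not
    significant)."""

    bottle_id: str
    significant: bool
    sr_flux: float | None = None
    sr_flux_sd: float | None = None
    c_flux: float | None = None
    c_flux_sd: float | None = None
    poc_contribution_pct: float | None = None


def estimate_background(
    series: TrapSeries, cutoff: float = DEFAULT_BACKGROUND_CUTOFF
) -> BackgroundEstimate:
    """Background = mean of all bottles strictly below the cutoff.

    SD is the sample standard deviation (n−1).  Estimated per trap, never
    pooled across traps.  Raises if fewer than two bottles qualify.
    """
    sub = [b.sr_conc for b in series.bottles if b.sr_conc < cutoff]
    if len(sub) < 2:
        raise ValueError(
            f"cannot-estimate-background: trap {series.trap_id!r} has "
            f"{len(sub)} bottle(s) below {cutoff} µg/mL (need >= 2)"
        )
    n = len(sub)
    mean = sum(sub) / n
    var = sum((x - mean) ** 2 for x in sub) / (n - 1)
    sd = math.sqrt(var)
    if sd == 0:
        logger.warning(
            "trap %s: background SD is 0; significance degenerates to "
            "'> mean' — consider the 1%% analytical-uncertainty floor",
            series.trap_id,
        )
    return BackgroundEstimate(mean=mean, sd=sd, n_bottles_used=n, cutoff=cutoff)


def flag_significant(series: TrapSeries, bg: BackgroundEstimate) -> dict[str, bool]:
    """Bottle is significantly Sr-elevated iff conc > mean + 2·SD (strict)."""
    threshold = bg.mean + 2.0 * bg.sd
    return {b.bottle_id: b.sr_conc > threshold for b in series.bottles}


def compute_flux(
    bottle: TrapBottle, bg: BackgroundEstimate, area: float = DEFAULT_COLLECTION_AREA
) -> tuple[float, float]:
    """Sr flux and its 1-sigma uncertainty for a significant bottle.

    flux = (conc − bg.mean) µg/mL × volume mL → µg, /1000 → mg,
    divided by (area m² × duration d).  The uncertainty combines the 1%
    analytical error on the measured concentration with the background SD
    in quadrature, then scales identically.
    """
    excess = bottle.sr_conc - bg.mean
    scale = bottle.volume_ml / 1000.0 / (area * bottle.duration_days)
    sr_flux = excess * scale
    sr_flux_sd = math.hypot(0.01 * bottle.sr_conc, bg.sd) * scale
    return sr_flux, sr_flux_sd


def estimate_carbon(
    sr_flux: float, sr_flux_sd: float, ratio: CSrRatio = CSrRatio()
) -> tuple[float, float]:
    """Convert an Sr flux to organic-carbon flux via the C:Sr ratio.

    Relative uncertainties of the Sr flux and the ratio combine in
    quadrature; a zero flux has zero uncertainty.
    """
    if sr_flux < 0:
        raise ValueError("sr_flux must be >= 0")
    c_flux = sr_flux * ratio.value
    if sr_flux == 0:
        return 0.0, 0.0
    rel = math.hypot(sr_flux_sd / sr_flux, ratio.sd / ratio.value)
    return c_flux, c_flux * rel


def poc_contribution(c_flux: float, total_poc_flux: float) -> float:
    """Percentage of the total POC flux explained by the carbon flux."""
    if total_poc_flux <= 0:
        raise ValueError("total POC flux must be positive")
    return 100.0 * c_flux / total_poc_flux


def carbonate_sr_bound(ca_elevation: float, sr_per_g: float = 1.0) -> float:
    """Upper bound on Sr contributed by dissolving CaCO₃.

    ``ca_elevation`` (µg Ca mL⁻¹ above background-only bottles) times the
    carbonate Sr content (mg Sr per g, applied per gram of measured Ca
    elevation) gives the maximum CaCO₃-derived Sr in µg mL⁻¹.
    """
    if ca_elevation < 0:
        raise ValueError("Ca elevation must be >= 0")
    return ca_elevation * sr_per_g * 1e-3


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at a number of decimals (reporting precision)."""
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor


def analyze_series(
    series: TrapSeries,
    cutoff: float = DEFAULT_BACKGROUND_CUTOFF,
    ratio: CSrRatio = CSrRatio(),
    total_poc_flux: dict[str, float] | None = None,
) -> tuple[BackgroundEstimate, list[FluxResult]]:
    """Full per-trap analysis: background, significance, fluxes, carbon.

    ``total_poc_flux`` optionally maps bottle_id to the total POC flux
    (mg C m⁻² d⁻¹) for that collection period, enabling the percent-of-POC
    column.  Fluxes are only computed for significant bottles.
    """
    bg = estimate_background(series, cutoff=cutoff)
    flags = flag_significant(series, bg)
    results: list[FluxResult] = []
    for bottle in series.bottles:
        if not flags[bottle.bottle_id]:
            results.append(FluxResult(bottle_id=bottle.bottle_id, significant=False))
            continue
        sr_flux, sr_sd = compute_flux(bottle, bg, area=series.collection_area)
        c_flux, c_sd = estimate_carbon(sr_flux, sr_sd, ratio)
        poc_pct = None
        if total_poc_flux and bottle.bottle_id in total_poc_flux:
            poc_pct = poc_contribution(c_flux, total_poc_flux[bottle.bottle_id])
        results.append(
            FluxResult(
                bottle_id=bottle.bottle_id,
                significant=True,
                sr_flux=sr_flux,
                sr_flux_sd=sr_sd,
                c_flux=c_flux,
                c_flux_sd=c_sd,
                poc_contribution_pct=poc_pct,
            )
        )
    return bg, results


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

TRAP_CSV_COLUMNS = [
    "trap_id", "bottle_id", "duration_days", "volume_ml",
    "sr_ug_per_ml", "ca_ug_per_ml",
]


def read_trap_csv(
    path: str | Path, collection_area: float = DEFAULT_COLLECTION_AREA
) -> list[TrapSeries]:
    """Load bottle series (one TrapSeries per trap_id, in file order)."""
    df = pd.read_csv(path)
    missing = set(TRAP_CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for trap_id, group in df.groupby("trap_id", sort=False):
        bottles = [
            TrapBottle(
                trap_id=str(trap_id),
                bottle_id=str(row.bottle_id),
                duration_days=float(row.duration_days),
                volume_ml=float(row.volume_ml),
                sr_conc=float(row.sr_ug_per_ml),
                ca_conc=float(row.ca_ug_per_ml)
                if "ca_ug_per_ml" in df.columns and pd.notna(row.ca_ug_per_ml)
                else None,
            )
            for row in group.itertuples()
        ]
        series.append(
            TrapSeries(
                trap_id=str(trap_id), bottles=bottles, collection_area=collection_area
            )
        )
    return series


def write_trap_csv(series: TrapSeries, path: str | Path) -> None:
    rows = [
        {
            "trap_id": b.trap_id,
            "bottle_id": b.bottle_id,
            "duration_days": b.duration_days,
            "volume_ml": b.volume_ml,
            "sr_ug_per_ml": b.sr_conc,
            "ca_ug_per_ml": b.ca_conc if b.ca_conc is not None else "",
        }
        for b in series.bottles
    ]
    pd.DataFrame(rows, columns=TRAP_CSV_COLUMNS).to_csv(path, index=False)


def flux_results_to_frame(results: list[FluxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bottle_id": r.bottle_id,
                "significant": r.significant,
                "sr_flux": r.sr_flux,
                "sr_flux_sd": r.sr_flux_sd,
                "c_flux": r.c_flux,
                "c_flux_sd": r.c_flux_sd,
                "poc_contribution_pct": r.poc_contribution_pct,
            }
            for r in results
        ]
    )
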
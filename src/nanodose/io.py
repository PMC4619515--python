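"""File I/O: size-distribution readers/writers, result export, fixtures.

Size distributions are two-column delimited text (diameter in nm, fraction
or intensity), comma / tab / whitespace separated, optional header, ``#``
comments. Results are written as diffable CSVs plus a JSON run manifest;
spreadsheet export is optional sugar (requires openpyxl).
"""

from __future__ import annotations

import json
import logging
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ConcentrationProfile, DoseTimeSeries, SizeDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "read_size_distribution",
    "write_size_distribution",
    "synth_distribution",
    "write_outputs",
]

_SPLIT = re.compile(r"[,;\t ]+")


def read_size_distribution(path: str | Path, weighting: str = "volume") -> SizeDistribution:
    """Read a two-column (diameter_nm, fraction) text file.

    Fractions are renormalized to sum to 1 (the scale factor is logged, so
    percent or raw-intensity columns are accepted). ``weighting`` declares
    how the file's fractions are weighted; no conversion is performed here.
    """
    path = Path(path)
    diameters: list[float] = []
    fractions: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = [p for p in _SPLIT.split(text) if p]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {text!r}")
            try:
                d, f = float(parts[0]), float(parts[1])
            except ValueError:
                if not diameters:
                    continue  # header row(s) before the first data row
                raise ValueError(f"{path}:{lineno}: non-numeric row {text!r}") from None
            if d <= 0 or f < 0:
                raise ValueError(
                    f"{path}:{lineno}: diameters must be > 0 and fractions >= 0, got {text!r}"
                )
            diameters.append(d)
            fractions.append(f)
    if not diameters:
        raise ValueError(f"{path}: no data rows found")
    fractions_arr = np.asarray(fractions, dtype=float)
    total = fractions_arr.sum()
    if total <= 0:
        raise ValueError(f"{path}: fractions sum to zero")
    if abs(total - 1.0) > 1e-9:
        logger.info("renormalizing %s fractions by factor %.6g", path.name, 1.0 / total)
    return SizeDistribution(
        diameters=np.asarray(diameters) * 1e-9,
        fractions=fractions_arr / total,
        weighting=weighting,
    )


def write_size_distribution(dist: SizeDistribution, path: str | Path) -> Path:
    """Write a distribution in the reader's two-column format (nm, fraction)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("diameter_nm,fraction\n")
        for d, f in zip(dist.diameters, dist.fractions):
            fh.write(f"{d * 1e9:.10g},{f:.12g}\n")
    return path


def synth_distribution(
    geometric_mean_nm: float,
    geometric_sd: float,
    bins: int = 25,
    seed: int | None = None,
    path: str | Path | None = None,
) -> SizeDistribution:
    """Deterministic lognormal number-weighted size distribution.

    Discretizes the lognormal over +/- 3 log-SD into ``bins`` midpoints with
    Gaussian (in log-diameter) weights. ``seed`` is accepted for API
    symmetry with other fixture generators but unused — the output depends
    only on the parameters. With ``geometric_sd`` close to 1 the result
    collapses to a single bin.
    """
    if geometric_mean_nm <= 0:
        raise ValueError("geometric_mean_nm must be > 0")
    if geometric_sd < 1:
        raise ValueError("geometric_sd must be >= 1")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    log_gm = math.log(geometric_mean_nm)
    log_sd = math.log(geometric_sd)
    if log_sd < 1e-9 or bins == 1:
        dist = SizeDistribution(
            diameters=np.array([geometric_mean_nm * 1e-9]),
            fractions=np.array([1.0]),
            weighting="number",
        )
    else:
        x = np.linspace(log_gm - 3.0 * log_sd, log_gm + 3.0 * log_sd, bins)
        weights = np.exp(-0.5 * ((x - log_gm) / log_sd) ** 2)
        dist = SizeDistribution(
            diameters=np.exp(x) * 1e-9, fractions=weights / weights.sum(), weighting="number"
        )
    if path is not None:
        write_size_distribution(dist, path)
    return dist


def write_outputs(
    profiles: list[ConcentrationProfile],
    timeseries: DoseTimeSeries,
    out_dir: str | Path,
    manifest: dict | None = None,
    excel: bool = False,
) -> dict[str, Path]:
    """Write profile.csv, timeseries.csv and manifest.json into ``out_dir``.

    The manifest records the resolved configuration (if supplied by the
    caller), the software version and a mass-balance echo. With
    ``excel=True`` an ``results.xlsx`` mirroring both CSVs is also written
    (requires the optional openpyxl dependency).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profile_df = pd.concat([p.to_dataframe() for p in profiles], ignore_index=True)
    series_df = timeseries.to_dataframe()

    paths = {
        "profile": out_dir / "profile.csv",
        "timeseries": out_dir / "timeseries.csv",
        "manifest": out_dir / "manifest.json",
    }
    profile_df.to_csv(paths["profile"], index=False, float_format="%.10g")
    series_df.to_csv(paths["timeseries"], index=False, float_format="%.10g")

    payload = {"version": __version__}
    if manifest:
        payload.update(manifest)
    if profiles:
        last = profiles[-1]
        h = float(last.depths[1] - last.depths[0]) if last.depths.size > 1 else float(last.depths[0] * 2)
        payload["final_suspended_mass_per_area_kg_m2"] = float(last.concentrations.sum() * h)
    with open(paths["manifest"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if excel:
        xlsx = out_dir / "results.xlsx"
        with pd.ExcelWriter(xlsx) as writer:
            series_df.to_excel(writer, sheet_name="timeseries", index=False)
            profile_df.to_excel(writer, sheet_name="profiles", index=False)
        paths["excel"] = xlsx
    return paths
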
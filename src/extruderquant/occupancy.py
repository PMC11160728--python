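"""Per-megabase chromatin occupancy tables and loop-extrusion arithmetic.

Combines absolute nuclear copy numbers (FCS-calibrated imaging) with
chromatin-bound fractions (FRAP / spot-bleach) into bound copies and
per-megabase densities for Condensin and Cohesin subunits and CTCF in
early G1 and G1, plus the closed-form loop-size and encounter-probability
arithmetic of the double-hierarchical loop model.

The published summary tables divide bound copies by ~15,800 Mb (two
daughter genomes of 7,900 Mb each) in BOTH cell-cycle stages, even though
the G1 stage nominally refers to a single nucleus; the default
``GenomeModel`` reproduces that convention and the divisor is fully
configurable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenomeModel:
    genome_mb_per_copy: float = 7900.0
    n_genome_copies: int = 2

    def __post_init__(self) -> None:
        if self.genome_mb_per_copy <= 0 or self.n_genome_copies <= 0:
            raise ValueError("genome size and copy number must be positive")

    @property
    def total_mb(self) -> float:
        return self.genome_mb_per_copy * self.n_genome_copies


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to the printed precision (not banker's)."""
    if not np.isfinite(x):
        return x
    factor = 10.0 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def bound_copies(nuclear_copies: float, bound_fraction: float) -> float:
    """Chromatin-bound copy number = nuclear copies x bound fraction."""
    if nuclear_copies < 0 or bound_fraction < 0:
        raise ValueError("inputs must be nonnegative")
    if bound_fraction > 1:
        raise ValueError("bound_fraction must be <= 1")
    return nuclear_copies * bound_fraction


def per_mb(bound: float, genome: GenomeModel) -> float:
    """Bound complexes per megabase assuming equal genome distribution."""
    return bound / genome.total_mb


def longterm_per_mb(per_mb_density: float, longterm_frac: float) -> float:
    """Long-term (stably) bound complexes per megabase."""
    if not 0.0 <= longterm_frac <= 1.0:
        raise ValueError("longterm_frac must be in [0, 1]")
    return per_mb_density * longterm_frac


def load_table_fixture() -> pd.DataFrame:
    """Raw (underived) columns of the packaged early G1 / G1 summary tables."""
    ref = importlib.resources.files("extruderquant.data") / "tables_1_2_raw.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def build_occupancy_table(records: pd.DataFrame,
                          genome: GenomeModel | None = None) -> pd.DataFrame:
    """Derive bound copies and per-Mb densities for each protein x stage row.

    The FRAP-derived bound fraction takes precedence; the spot-bleach value
    is the fallback when no exponential fit was obtainable (e.g. the
    Condensin II kleisin in early G1).  Rows with no bound fraction at all
    are flagged (``flag`` column), not dropped.  Display columns
    (``per_mb_display`` etc.) are rounded half-up to 1 decimal as printed.
    """
    if genome is None:
        genome = GenomeModel()
    out = records.copy()
    if len(out) == 0:
        for col in ("bound_fraction_used", "bound_copies", "per_mb",
                    "per_mb_display", "longterm_per_mb",
                    "longterm_per_mb_display", "flag"):
            out[col] = pd.Series(dtype=float)
        return out

    frap = pd.to_numeric(out.get("bound_frac_frap"), errors="coerce")
    spot = pd.to_numeric(out.get("bound_frac_spotbleach"), errors="coerce")
    used = frap.where(frap.notna(), spot)
    out["bound_fraction_used"] = used
    out["flag"] = np.where(used.isna(), "no bound fraction", "")

    copies = pd.to_numeric(out["nuclear_copies"], errors="coerce")
    bc = copies * used
    out["bound_copies"] = bc
    out["bound_copies_display"] = bc.round(0)
    dens = bc / genome.total_mb
    out["per_mb"] = dens
    out["per_mb_display"] = dens.map(lambda v: round_half_up(v, 1))

    lt = pd.to_numeric(out.get("longterm_frac"), errors="coerce")
    ltd = dens * lt
    out["longterm_per_mb"] = ltd
    out["longterm_per_mb_display"] = ltd.map(lambda v: round_half_up(v, 1))
    return out


def loop_size(speed_kb_per_s: float, residence_time_s: float) -> float:
    """Expected loop size (kb) = extrusion speed x residence time."""
    if speed_kb_per_s < 0 or residence_time_s < 0:
        raise ValueError("inputs must be nonnegative")
    return speed_kb_per_s * residence_time_s


def encounter_probability(density_per_mb: float, loop_kb: float) -> float:
    """Probability a random extruder's loop overlaps at least one neighbour.

    Under Poisson placement of ``density_per_mb`` extruders per Mb, the
    chance that none of them falls within a window of ``loop_kb`` is
    exp(-density * loop_kb / 1000); the complement is the encounter
    probability.  Monotone nondecreasing in both arguments, bounded in [0, 1).
    """
    if density_per_mb < 0 or loop_kb < 0:
        raise ValueError("inputs must be nonnegative")
    return float(1.0 - np.exp(-density_per_mb * loop_kb / 1000.0))
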
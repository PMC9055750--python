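"""Aneuploidy screening from binned read counts.

Each biopsy's ~1.5 million fragments are tallied into fixed genome bins,
normalized against a reference profile, and rescaled so the genome-wide
median ratio is 1. A chromosome's median bin ratio then estimates its
copy state: 1.0 for disomy, 1.5 for trisomy, 0.5 for monosomy, and
intermediate values for mosaics (a mosaic fraction f shifts the ratio to
1 +/- f/2, so f is estimated as 2|ratio - 1|).

Mosaicism bands are a reconstruction of common PGT-A practice, not a
published clinical threshold set; all bands are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNVBands:
    """Per-chromosome ratio bands for copy-state calling."""

    euploid: tuple[float, float] = (0.9, 1.1)
    mosaic_gain: tuple[float, float] = (1.15, 1.35)   # half-open (lo, hi]
    full_gain_above: float = 1.35
    mosaic_loss: tuple[float, float] = (0.65, 0.85)   # [lo, hi)
    full_loss_below: float = 0.65


@dataclass
class ChromosomeCall:
    chrom: str
    ratio: float
    call: str                     # euploid | gain | loss | mosaic_gain | mosaic_loss
    mosaic_fraction_estimate: float
    borderline: bool = False


@dataclass
class CNVProfile:
    """Normalized profile and per-chromosome calls for one embryo."""

    embryo: str
    bins: pd.DataFrame            # chrom, start, end, count, ratio
    chromosomes: list[ChromosomeCall]
    notes: dict = field(default_factory=dict)

    @property
    def is_euploid(self) -> bool:
        return all(c.call == "euploid" for c in self.chromosomes)

    @property
    def call(self) -> str:
        """Worst-case summary call over chromosomes."""
        order = ["gain", "loss", "mosaic_gain", "mosaic_loss", "euploid"]
        calls = {c.call for c in self.chromosomes}
        for label in order:
            if label in calls:
                return label
        return "euploid"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.chrom, c.ratio, c.call, c.mosaic_fraction_estimate,
              c.borderline) for c in self.chromosomes],
            columns=["chrom", "ratio", "call", "mosaic_fraction", "borderline"])


def normalize_bins(raw: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Ratio of observed to reference bin fractions, median-rescaled to 1.

    ``raw`` and ``reference`` must share the same binning (chrom, start,
    end); bins with a zero reference count are masked (ratio NaN) and
    logged. Normalization is scale-invariant in both inputs.
    """
    if len(raw) != len(reference) or not (
            raw[["chrom", "start"]].reset_index(drop=True)
            .equals(reference[["chrom", "start"]].reset_index(drop=True))):
        raise ValueError("raw and reference profiles use different binnings")
    count = raw["count"].to_numpy(dtype=float)
    ref = reference["count"].to_numpy(dtype=float)
    total, ref_total = count.sum(), ref.sum()
    if total <= 0 or ref_total <= 0:
        raise ValueError("profile totals must be positive")
    masked = ref <= 0
    if masked.any():
        logger.info("masked %d bins with zero reference counts", int(masked.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (count / total) / (ref / ref_total)
    ratio[masked] = np.nan
    med = np.nanmedian(ratio)
    if med > 0:
        ratio = ratio / med
    out = raw.copy()
    out["ratio"] = ratio
    return out


def call_chromosome(ratio: float, bands: CNVBands | None = None) -> ChromosomeCall:
    """Classify one chromosome's normalized ratio into a copy-state call.

    Ratios falling in the unassigned gaps between bands are assigned to
    the nearest category by distance and flagged borderline.
    """
    b = bands or CNVBands()
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    frac = float(np.clip(2.0 * abs(ratio - 1.0), 0.0, 1.0))
    call: str | None = None
    if b.euploid[0] <= ratio <= b.euploid[1]:
        call = "euploid"
    elif b.mosaic_gain[0] < ratio <= b.mosaic_gain[1]:
        call = "mosaic_gain"
    elif ratio > b.full_gain_above:
        call = "gain"
    elif b.mosaic_loss[0] <= ratio < b.mosaic_loss[1]:
        call = "mosaic_loss"
    elif ratio < b.full_loss_below:
        call = "loss"
    if call is not None:
        return ChromosomeCall("", ratio, call, frac, borderline=False)
    # gap zone: nearest category by distance to band edges
    candidates = {
        "euploid": min(abs(ratio - b.euploid[0]), abs(ratio - b.euploid[1])),
        "mosaic_gain": min(abs(ratio - b.mosaic_gain[0]),
                           abs(ratio - b.mosaic_gain[1])),
        "mosaic_loss": min(abs(ratio - b.mosaic_loss[0]),
                           abs(ratio - b.mosaic_loss[1])),
    }
    call = min(candidates, key=lambda k: (candidates[k], k))
    return ChromosomeCall("", ratio, call, frac, borderline=True)


def screen_embryo(
    raw: pd.DataFrame,
    reference: pd.DataFrame,
    embryo: str = "E1",
    bands: CNVBands | None = None,
) -> CNVProfile:
    """Normalize one embryo's binned counts and call every chromosome."""
    norm = normalize_bins(raw, reference)
    calls = []
    for chrom, grp in norm.groupby("chrom", sort=False):
        med = float(np.nanmedian(grp["ratio"].to_numpy()))
        c = call_chromosome(med, bands)
        calls.append(ChromosomeCall(chrom, c.ratio, c.call,
                                    c.mosaic_fraction_estimate, c.borderline))
    return CNVProfile(embryo=embryo, bins=norm, chromosomes=calls)
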
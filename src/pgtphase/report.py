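"""Transfer decisions and cohort-level arithmetic.

A blastocyst is transferable when its monogenic diagnosis is unaffected
(carrier or noncarrier) AND its aneuploidy screen is euploid; mosaic
embryos are withheld. The module also ships the per-family outcome table
of the 36-couple clinical cohort and reproduces its summary rates.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass

import pandas as pd

from .calling import EmbryoCall
from .cnv import CNVProfile

logger = logging.getLogger(__name__)

_FUNNEL = ("oocytes", "mii", "fertilized_2pn", "cleavage", "blastocysts",
           "biopsied", "unaffected", "transferable")


@dataclass(frozen=True)
class FamilyOutcome:
    """One family's counting record (one row of the outcomes table)."""

    family: str
    pgt_cycles: int
    fet_cycles: int
    oocytes: int
    mii: int
    fertilized_2pn: int
    cleavage: int
    blastocysts: int
    biopsied: int
    unaffected: int
    transferable: int
    clinical_pregnancy: int
    live_birth: int
    pgt_m_result: str = "NA"
    note: str = ""

    def __post_init__(self) -> None:
        values = [getattr(self, k) for k in _FUNNEL]
        if any(v < 0 for v in values):
            raise ValueError(f"family {self.family}: negative count")
        for a, b, ka, kb in zip(values, values[1:], _FUNNEL, _FUNNEL[1:]):
            if b > a:
                raise ValueError(
                    f"family {self.family}: {kb}={b} exceeds {ka}={a}")


def load_cohort_outcomes() -> list[FamilyOutcome]:
    """The packaged per-family outcomes of the 36-couple cohort."""
    ref = importlib.resources.files("pgtphase") / "data" / "cohort_outcomes.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(FamilyOutcome(
            family=str(row.family),
            pgt_cycles=int(row.pgt_cycles), fet_cycles=int(row.fet_cycles),
            oocytes=int(row.oocytes), mii=int(row.mii),
            fertilized_2pn=int(row.fertilized_2pn),
            cleavage=int(row.cleavage), blastocysts=int(row.blastocysts),
            biopsied=int(row.biopsied), unaffected=int(row.unaffected),
            transferable=int(row.transferable),
            clinical_pregnancy=int(row.clinical_pregnancy),
            live_birth=int(row.live_birth),
            pgt_m_result=str(row.pgt_m_result),
            note="" if str(row.note) in (".", "nan") else str(row.note)))
    return out


def decide_transferable(
    embryo_calls: list[EmbryoCall],
    cnv_profiles: dict[str, CNVProfile],
) -> dict[str, bool]:
    """Per-embryo transfer eligibility.

    Transferable iff the final monogenic status is carrier or noncarrier
    AND the CNV screen is euploid (mosaics are withheld). Embryos missing
    either call are excluded with a logged count.
    """
    decisions: dict[str, bool] = {}
    n_missing = 0
    for call in embryo_calls:
        profile = cnv_profiles.get(call.embryo)
        if profile is None:
            n_missing += 1
            continue
        decisions[call.embryo] = (
            call.final_status in ("carrier", "noncarrier")
            and profile.is_euploid)
    if n_missing:
        logger.info("excluded %d embryos lacking a CNV profile", n_missing)
    return decisions


def _pct(num: int, den: int) -> float | str:
    if den == 0:
        return "undefined"
    return round(100.0 * num / den, 1)


def summarize_cohort(outcomes: list[FamilyOutcome]) -> dict:
    """Aggregate the per-family table into the cohort's summary rates.

    Every rate is computed from the summed numerator and denominator
    columns (percentages and means to one decimal). Zero denominators are
    reported as ``"undefined"`` rather than propagating NaN.
    """
    if not outcomes:
        raise ValueError("need at least one family")
    totals = {
        key: sum(getattr(o, key) for o in outcomes)
        for key in ("pgt_cycles", "fet_cycles", *_FUNNEL,
                    "clinical_pregnancy", "live_birth")
    }
    n = len(outcomes)
    report = {
        "n_families": n,
        "totals": totals,
        "unaffected_pct": _pct(totals["unaffected"], totals["biopsied"]),
        "euploid_of_unaffected_pct": _pct(
            totals["transferable"], totals["unaffected"]),
        "mean_blastocysts_per_couple": (
            "undefined" if n == 0 else round(totals["biopsied"] / n, 1)),
        "mean_transferable_per_couple": (
            "undefined" if n == 0 else round(totals["transferable"] / n, 1)),
        "clinical_pregnancy_rate_pct": _pct(
            totals["clinical_pregnancy"], totals["fet_cycles"]),
        "live_birth_rate_pct": _pct(
            totals["live_birth"], totals["fet_cycles"]),
        "notes": [
            "all rates computed from summed numerator/denominator columns; "
            "where a source table's printed rate disagrees with its own "
            "printed fraction, the fraction is authoritative",
        ],
    }
    return report


def p_none_affected(n_embryos: int) -> float:
    """Probability that no embryo of a carrier x carrier couple is affected.

    Each embryo is independently affected with probability 1/4, so the
    chance that an n-embryo cohort contains no phasing reference is
    (3/4)^n — about 10% even with 8 embryos.
    """
    if n_embryos < 0 or int(n_embryos) != n_embryos:
        raise ValueError(f"n_embryos must be a non-negative integer, got {n_embryos}")
    return math.pow(0.75, int(n_embryos))


def report_markdown(summary: dict) -> str:
    """Render the cohort summary as a small Markdown report."""
    t = summary["totals"]
    lines = [
        "# PGT cohort summary",
        "",
        f"Families: {summary['n_families']}  |  PGT cycles: {t['pgt_cycles']}"
        f"  |  FET cycles: {t['fet_cycles']}",
        "",
        "| quantity | value |",
        "|---|---|",
        f"| oocytes retrieved | {t['oocytes']} |",
        f"| biopsied blastocysts | {t['biopsied']} |",
        f"| unaffected | {t['unaffected']} ({summary['unaffected_pct']}%) |",
        f"| euploid of unaffected | {t['transferable']}"
        f" ({summary['euploid_of_unaffected_pct']}%) |",
        f"| mean blastocysts / couple | {summary['mean_blastocysts_per_couple']} |",
        f"| mean transferable / couple | {summary['mean_transferable_per_couple']} |",
        f"| clinical pregnancy rate / FET | {summary['clinical_pregnancy_rate_pct']}% |",
        f"| live birth rate / FET | {summary['live_birth_rate_pct']}% |",
    ]
    return "\n".join(lines) + "\n"
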
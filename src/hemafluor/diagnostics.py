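"""Clinical comparison: three-band spectral summaries, patient-vs-patient
classification with a fixed interpretation vocabulary, RBC/MCH arithmetic,
and concordance of the spectral verdicts with complete-blood-count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .photophysics import integrate_intensity
from .spectra import Spectrum1D
from .synthetic import CBCRecord, mch_range_for_age

# Diagnostic bands in nm: half-open on the right except the last (closed).
BAND_HB_OXY = (400.0, 600.0)  # hemoglobin + oxyhemoglobin
BAND_DEOXY = (600.0, 700.0)  # deoxyhemoglobin
BAND_PLASMA = (800.0, 900.0)  # plasma + water
BAND_UNASSIGNED = (700.0, 800.0)  # named by no region; reported separately

BAND_NAMES = ("hb_oxy", "deoxy", "plasma")

#: Closed interpretation vocabulary, per band, for winner and loser.
INTERPRETATIONS: dict[str, dict[str, str]] = {
    "hb_oxy": {
        "winner": "higher Hb/HbO2",
        "loser": "lower Hb/HbO2 (possible anemia)",
        "tie": "comparable Hb/HbO2",
    },
    "deoxy": {
        "winner": "higher deoxy-Hb (possible hypoxia)",
        "loser": "lower deoxy-Hb (better oxygenation)",
        "tie": "comparable deoxy-Hb",
    },
    "plasma": {
        "winner": "higher plasma content (lower hematocrit)",
        "loser": "lower plasma content (higher hematocrit)",
        "tie": "comparable plasma content",
    },
}


@dataclass(frozen=True)
class BandSummary:
    """Integrated intensities of the three diagnostic bands (a.u. nm)."""

    band_hb_oxy: float
    band_deoxy: float
    band_plasma: float
    band_unassigned: float
    source: str | None = None


@dataclass
class ComparisonReport:
    """Per-band winners and interpretation strings for a patient pair."""

    winners: dict[str, str]  # band -> patient_1 | patient_2 | tie
    interpretations: dict[str, dict[str, str]]  # band -> {patient_1, patient_2}
    tie_threshold: float
    source: str | None = None
    uv_absolute_comparison: bool = False
    concordance: dict | None = field(default=None)


def band_summary(s: Spectrum1D) -> BandSummary:
    """Trapezoidal integrals over the 400-600 / 600-700 / 800-900 nm bands.

    The 700-800 nm interval belongs to no named band and is reported
    separately as ``band_unassigned``.
    """
    lo, hi = s.span
    if lo > BAND_HB_OXY[0] or hi < BAND_PLASMA[1]:
        raise ValueError(
            f"spectrum span [{lo}, {hi}] nm does not cover the 400-900 nm diagnostic range"
        )
    return BandSummary(
        band_hb_oxy=integrate_intensity(s, *BAND_HB_OXY),
        band_deoxy=integrate_intensity(s, *BAND_DEOXY),
        band_plasma=integrate_intensity(s, *BAND_PLASMA),
        band_unassigned=integrate_intensity(s, *BAND_UNASSIGNED),
        source=s.source,
    )


def _relative_difference(a: float, b: float) -> float:
    scale = max(abs(a), abs(b))
    return 0.0 if scale == 0.0 else abs(a - b) / scale


def _band_values(b: BandSummary) -> dict[str, float]:
    return {
        "hb_oxy": b.band_hb_oxy,
        "deoxy": b.band_deoxy,
        "plasma": b.band_plasma,
    }


def compare_patients(
    b1: BandSummary,
    b2: BandSummary,
    tie_threshold: float = 0.01,
) -> ComparisonReport:
    """Per-band comparison of two patients' band summaries.

    The larger integral wins a band; a relative difference below
    ``tie_threshold`` is a tie. Under a UV source the sign of a band
    integral is ambiguous (difference spectra), so absolute values are
    compared and the report flags that.
    """
    if b1.source != b2.source:
        raise ValueError(f"source mismatch: {b1.source!r} vs {b2.source!r}")
    use_abs = b1.source == "UV"

    winners: dict[str, str] = {}
    interps: dict[str, dict[str, str]] = {}
    v1, v2 = _band_values(b1), _band_values(b2)
    for band in BAND_NAMES:
        a, b = v1[band], v2[band]
        if use_abs:
            a, b = abs(a), abs(b)
        if _relative_difference(a, b) < tie_threshold:
            winners[band] = "tie"
            interps[band] = {
                "patient_1": INTERPRETATIONS[band]["tie"],
                "patient_2": INTERPRETATIONS[band]["tie"],
            }
        elif a > b:
            winners[band] = "patient_1"
            interps[band] = {
                "patient_1": INTERPRETATIONS[band]["winner"],
                "patient_2": INTERPRETATIONS[band]["loser"],
            }
        else:
            winners[band] = "patient_2"
            interps[band] = {
                "patient_1": INTERPRETATIONS[band]["loser"],
                "patient_2": INTERPRETATIONS[band]["winner"],
            }

    return ComparisonReport(
        winners=winners,
        interpretations=interps,
        tie_threshold=tie_threshold,
        source=b1.source,
        uv_absolute_comparison=use_abs,
    )


def rbc_count(total_hb_gL: float, mch_pg: float) -> float:
    """RBC count per liter: total hemoglobin (g/L) over mean corpuscular
    hemoglobin (pg converted to g)."""
    if mch_pg <= 0:
        raise ValueError("mch_pg must be positive")
    if total_hb_gL < 0:
        raise ValueError("total hemoglobin must be non-negative")
    return total_hb_gL / (mch_pg * 1e-12)


def rbc_count_1e6_per_ul(total_hb_gL: float, mch_pg: float) -> float:
    """RBC count in the clinical 10^6 cells/uL convention."""
    return rbc_count(total_hb_gL, mch_pg) / 1e12


def implied_mch(c: CBCRecord) -> float:
    """Mean corpuscular hemoglobin (pg) implied by a record's Hb and RBC.

    Hb in g/dL is converted to g/L (x10); RBC in 10^6/uL to cells/L (x1e12);
    the quotient is returned in pg. Exact algebraic inverse of
    :func:`rbc_count`.
    """
    if c.hb_gdl <= 0 or c.rbc_1e6_per_ul <= 0:
        raise ValueError("record must carry positive Hb and RBC values")
    return (c.hb_gdl * 10.0) / (c.rbc_1e6_per_ul * 1e12) * 1e12


def mch_reference_range(age_years: float) -> tuple[float, float]:
    """Age-appropriate MCH reference range (pg)."""
    return mch_range_for_age(age_years)


def _ordering(a: float, b: float, tie_threshold: float) -> str:
    if _relative_difference(a, b) < tie_threshold:
        return "tie"
    return "patient_1" if a > b else "patient_2"


def cbc_concordance(
    c1: CBCRecord,
    c2: CBCRecord,
    report: ComparisonReport,
    tie_threshold: float = 0.01,
) -> ComparisonReport:
    """Annotate a comparison report with CBC agreement flags.

    Per band: the CBC counterpart of the 400-600 nm band is hemoglobin
    concentration, and of the 800-900 nm band the inverse hematocrit
    ordering (lower hematocrit implies more plasma). The 600-700 nm
    deoxyhemoglobin band has no CBC counterpart — it reflects oxygen
    dissociation, not cell counts — and is always flagged functional-only.
    The implied MCH of each record is reported with its in/out-of-range
    status for the subject's age.
    """
    flags: dict[str, str] = {}

    cbc_hb_winner = _ordering(c1.hb_gdl, c2.hb_gdl, tie_threshold)
    # lower hematocrit -> higher plasma fraction -> expected plasma-band winner
    cbc_plasma_winner = _ordering(c2.hct_pct, c1.hct_pct, tie_threshold)

    for band, cbc_winner in (("hb_oxy", cbc_hb_winner), ("plasma", cbc_plasma_winner)):
        spectral = report.winners[band]
        if cbc_winner == "tie" or spectral == "tie":
            flags[band] = "indeterminate"
        else:
            flags[band] = "agree" if spectral == cbc_winner else "disagree"
    flags["deoxy"] = "functional-only"

    mch_info = {}
    for label, rec in (("patient_1", c1), ("patient_2", c2)):
        mch = implied_mch(rec)
        lo, hi = mch_reference_range(rec.age_years)
        mch_info[label] = {
            "implied_mch_pg": mch,
            "reference_range_pg": [lo, hi],
            "status": "in_range" if lo <= mch <= hi else "out_of_range",
        }

    report.concordance = {"band_flags": flags, "implied_mch": mch_info}
    return report
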
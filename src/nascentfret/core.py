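"""Measurement math for donor-quench FRET on nascent chains.

Implements the assay's calculation chain for one matched quadruple:

1. peak extraction — mean of the five highest emission intensities
   (~475 nm) of each scan;
2. nascent-chain concentration from scintillation counting,
   [RNC] = (cpm_S - cpm_B) / (CE * SA * vol), in nM;
3. net blank-corrected fluorescence per nM, F = (peak_S - peak_B)/[RNC]
   (D is corrected with the BD blank, DA with the BDA blank);
4. FRET efficiency by donor quenching, E = 1 - F_DA / F_D;
5. readthrough QC — accept only quadruples whose D/DA readthrough ratio
   falls inside the probe-site-specific band, since a suppression
   mismatch inflates or deflates apparent FRET through zero-FRET stalled
   chains.

Negative intermediate values and efficiencies are reported with flags,
never clipped, so replicate averages stay unbiased.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .errors import UnusableExperimentError
from .types import (
    ConditionKey,
    ExperimentBundle,
    FretResult,
    PeakIntensity,
    RncConcentration,
    SpectrumRecord,
)

__all__ = [
    "extract_peak_intensity",
    "rnc_concentration",
    "net_intensity_per_nm",
    "fret_efficiency",
    "qc_readthrough",
    "qc_band",
    "compute_experiment_fret",
]

#: Number of top emission intensities averaged into the peak value.
N_PEAK_POINTS = 5

#: D/DA readthrough-ratio acceptance bands per acceptor probe site
#: (inclusive).  The tighter band for Asp567 reflects that probe's
#: greater sensitivity to stall mismatch; Thr389 (the CFP tether
#: control) reuses the Arg487 band.
_QC_BANDS = {
    487: (0.80, 1.20),
    567: (0.85, 1.15),
    389: (0.80, 1.20),
}


def extract_peak_intensity(spectrum: SpectrumRecord) -> PeakIntensity:
    """Average the five highest intensities of an emission scan.

    Ties are broken toward lower wavelength.  Records which wavelengths
    contributed; with the CFP line shape these cluster in the 470-482 nm
    region around the ~475 nm emission maximum.
    """
    inten = spectrum.intensity
    if inten.size < N_PEAK_POINTS:
        raise ValueError(
            f"need at least {N_PEAK_POINTS} spectral points, got {inten.size}"
        )
    # stable sort on (-intensity, wavelength): equal intensities resolve
    # to the lower wavelength
    order = np.lexsort((spectrum.wavelength, -inten))
    top = order[:N_PEAK_POINTS]
    return PeakIntensity(
        value=float(inten[top].mean()),
        wavelengths_used=tuple(int(w) for w in spectrum.wavelength[top]),
    )


def rnc_concentration(
    cpm_s: float, cpm_b: float, ce: float, sa: float, vol: float
) -> RncConcentration:
    """Nascent-chain concentration from |14C| scintillation counts.

    [RNC] = (cpm_S - cpm_B) / (CE * SA * vol)  [nM]

    ``cpm_s`` is the D or DA sample count rate, ``cpm_b`` the matching
    blank (BD or BDA).  A non-positive result (cpm_S <= cpm_B) is
    returned flagged rather than clipped.
    """
    if not 0 < ce <= 1:
        raise ValueError(f"counting efficiency must be in (0, 1], got {ce}")
    if sa <= 0:
        raise ValueError(f"specific activity must be positive, got {sa}")
    if vol <= 0:
        raise ValueError(f"volume must be positive, got {vol}")
    value = (cpm_s - cpm_b) / (ce * sa * vol)
    return RncConcentration(
        value=float(value),
        cpm_s=float(cpm_s),
        cpm_b=float(cpm_b),
        ce=ce,
        sa=sa,
        vol=vol,
        flagged=value <= 0,
    )


def net_intensity_per_nm(
    sample_peak: PeakIntensity,
    blank_peak: PeakIntensity,
    conc: RncConcentration,
) -> float:
    """Blank-corrected peak fluorescence per nM nascent chain.

    (peak_sample - peak_blank) / [RNC]; raises
    :class:`~nascentfret.errors.UnusableExperimentError` when the
    concentration is non-positive (the Eq.-for-concentration flag).
    """
    if conc.value <= 0:
        raise UnusableExperimentError(
            f"non-positive nascent-chain concentration ({conc.value:.4g} nM, "
            f"cpm_S={conc.cpm_s:.1f}, cpm_B={conc.cpm_b:.1f})",
            stage="rnc_concentration",
        )
    return (sample_peak.value - blank_peak.value) / conc.value


def fret_efficiency(f_da: float, f_d: float) -> float:
    """Donor-quench FRET efficiency, E = 1 - F_DA / F_D.

    Not clipped to [0, 1]: measurement noise can produce small negative
    values, which must be retained for unbiased replicate averaging.
    """
    if f_d <= 0:
        raise UnusableExperimentError(
            f"donor-only net intensity must be positive, got {f_d:.4g}",
            stage="fret_efficiency",
        )
    return 1.0 - f_da / f_d


def qc_band(probe_site: int) -> Tuple[float, float]:
    """Inclusive D/DA readthrough-ratio acceptance band for a probe site."""
    try:
        return _QC_BANDS[probe_site]
    except KeyError:
        raise ValueError(
            f"no QC band defined for probe site {probe_site}"
        ) from None


def qc_readthrough(readthrough_ratio: float, probe_site: int) -> bool:
    """Whether a quadruple passes the readthrough-mismatch QC band."""
    if readthrough_ratio <= 0:
        raise ValueError("readthrough ratio must be positive")
    lo, hi = qc_band(probe_site)
    return lo <= readthrough_ratio <= hi


def compute_experiment_fret(bundle: ExperimentBundle) -> FretResult:
    """Full FRET calculation for one matched quadruple.

    Peak-extracts all four spectra, corrects D with the BD blank and DA
    with the BDA blank, converts counts to concentrations, forms the
    per-nM net intensities and returns E = 1 - F_DA/F_D together with the
    QC verdict.  QC failure does not prevent computation — the result
    carries ``qc_pass=False`` and downstream statistics exclude it.
    """
    peaks = {role: extract_peak_intensity(bundle[role].spectrum) for role in bundle.samples}
    conc_d = rnc_concentration(
        bundle["D"].cpm, bundle["BD"].cpm,
        bundle["D"].ce, bundle["D"].sa, bundle["D"].vol,
    )
    conc_da = rnc_concentration(
        bundle["DA"].cpm, bundle["BDA"].cpm,
        bundle["DA"].ce, bundle["DA"].sa, bundle["DA"].vol,
    )
    f_d = net_intensity_per_nm(peaks["D"], peaks["BD"], conc_d)
    f_da = net_intensity_per_nm(peaks["DA"], peaks["BDA"], conc_da)
    e = fret_efficiency(f_da, f_d)

    flags = []
    if conc_d.flagged or conc_da.flagged:
        flags.append("nonpositive_concentration")
    if f_da < 0:
        flags.append("negative_net_intensity")
    if e < 0:
        flags.append("negative_efficiency")

    ratio = bundle.readthrough_ratio
    return FretResult(
        experiment_id=bundle.experiment_id,
        condition=bundle.condition,
        e_fret=float(e),
        f_d=float(f_d),
        f_da=float(f_da),
        conc_d=conc_d.value,
        conc_da=conc_da.value,
        readthrough_ratio=float(ratio),
        qc_pass=qc_readthrough(ratio, bundle.condition.probe_site),
        flags=tuple(flags),
    )
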
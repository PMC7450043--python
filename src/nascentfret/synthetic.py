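"""Generative model of the matched-quadruple FRET assay.

Simulates everything the measurement pipeline consumes — CFP emission
spectra, scintillation counts and reaction metadata for the four matched
reactions (D, DA, BD, BDA) — from a small set of physical parameters, so
the full analysis chain can be verified round-trip against closed-form
oracles without laboratory data.

Generative picture
------------------
A translation reaction contains ``rnc_conc`` nM of readthrough chains
(amber codon suppressed; these carry the |14C| label and, in DA, the
acceptor dye) plus ``s`` stalled chains per readthrough chain (terminated
at the amber codon: fluorescent donor, no label, no acceptor, zero FRET).
Donor fluorescence per nM readthrough chain therefore comes out inflated
by the unlabeled stalled chains:

* D reaction:   fluorescent chains = rnc_conc * (1 + s_D)
* DA reaction:  fluorescent signal = rnc_conc * ((1 - E_chain) + s_DA)
* BD/BDA:       background only (non-fluorescent CFP variant)

Counts measure only labeled (readthrough) chains, so the pipeline's
per-nM fluorescence ratio yields the *apparent* FRET

    E_app = 1 - ((1 - E_chain) + s_DA) / (1 + s_D),

which reduces to E_chain / (1 + s) for matched stalls — the quantity
:func:`apparent_fret_oracle` returns and the measurement pipeline must
reproduce.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleInversionError, MissingConditionError
from .fixtures import GroundTruthTable, REFERENCE_BANDC_FRACTIONS
from .types import (
    ConditionKey,
    ExperimentBundle,
    ReactionSample,
    ReactionSet,
    SpectrumRecord,
    ROLES,
    TEMP_MAX,
    TEMP_MIN,
    wavelength_grid,
)

__all__ = [
    "GenerativeParams",
    "apparent_fret_oracle",
    "invert_apparent_fret",
    "cfp_line_shape",
    "simulate_spectrum",
    "expected_cpm",
    "simulate_counts",
    "simulate_reaction_set",
    "simulate_experiment_series",
    "simulate_thermal_series",
    "simulate_blot_table",
]

#: Reference temperature for donor brightness, degrees C.
REFERENCE_TEMPERATURE = 25.0


@dataclass(frozen=True)
class GenerativeParams:
    """Physical parameters of one simulated reaction quadruple.

    Attributes
    ----------
    s_d, s_da
        Stalled-to-readthrough chain ratio in the D and DA reactions.
    rnc_conc
        True readthrough-chain (RNC) concentration, nM.
    donor_brightness
        Peak donor intensity per nM fluorescent chain at 25 C, arbitrary
        fluorometer units.
    brightness_temp_coeff
        Fractional donor-brightness loss per degree C above 25 C (CFP
        fluorescence falls reversibly with temperature).
    bg_level
        Flat baseline fluorescence (buffer + ribosome scatter).
    cpm_background
        Scintillation background, counts/min.
    sa
        Specific activity of the labeled lysine, dpm/pmol.
    ce
        Counting efficiency (~0.95 for |14C|).
    vol
        Counted sample volume, ml.
    noise_cv
        Fractional Gaussian noise applied per wavelength to spectra.
    poisson_counts
        Whether realized cpm are Poisson draws (False = expectation).
    """

    s_d: float = 0.1
    s_da: float = 0.1
    rnc_conc: float = 100.0
    donor_brightness: float = 120.0
    brightness_temp_coeff: float = 0.01
    bg_level: float = 500.0
    cpm_background: float = 100.0
    sa: float = 300.0
    ce: float = 0.95
    vol: float = 0.5
    noise_cv: float = 0.02
    poisson_counts: bool = True

    def __post_init__(self):
        if self.s_d < 0 or self.s_da < 0:
            raise ValueError("stall ratios must be >= 0")
        if self.rnc_conc <= 0:
            raise ValueError("rnc_conc must be positive")
        if not 0 < self.ce <= 1:
            raise ValueError("counting efficiency must be in (0, 1]")
        if self.sa <= 0 or self.vol <= 0:
            raise ValueError("sa and vol must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.donor_brightness <= 0:
            raise ValueError("donor_brightness must be positive")

    def quiet(self) -> "GenerativeParams":
        """Noise-free copy (deterministic spectra and counts)."""
        return replace(self, noise_cv=0.0, poisson_counts=False)

    def brightness_at(self, temperature: float) -> float:
        """Donor brightness at ``temperature``, linear loss from 25 C."""
        factor = 1.0 - self.brightness_temp_coeff * (
            temperature - REFERENCE_TEMPERATURE
        )
        return self.donor_brightness * max(factor, 0.0)

    @property
    def readthrough_ratio(self) -> float:
        """Reported D/DA readthrough ratio.

        With stall ratio s, the readthrough fraction of a reaction is
        1/(1+s); the D-to-DA ratio of those fractions is
        (1 + s_DA)/(1 + s_D).  Matched stalls give 1.0.
        """
        return (1.0 + self.s_da) / (1.0 + self.s_d)


def apparent_fret_oracle(e_chain: float, s_d: float, s_da: float) -> float:
    """Noise-free apparent FRET the pipeline reports for given truth.

    Stalled chains fluoresce as unquenched donors but carry no label, so
    per-nM donor fluorescence is inflated by the stall ratio in each
    reaction:

        E_app = 1 - ((1 - E_chain) + s_DA) / (1 + s_D)

    For matched stalls (s_D = s_DA = s) this is E_chain / (1 + s); a
    readthrough mismatch (s_D != s_DA) biases the result, which is what
    the D/DA-ratio QC band guards against.
    """
    if not 0.0 <= e_chain <= 1.0:
        raise ValueError(f"e_chain must be in [0, 1], got {e_chain}")
    if s_d < 0 or s_da < 0:
        raise ValueError("stall ratios must be >= 0")
    return 1.0 - ((1.0 - e_chain) + s_da) / (1.0 + s_d)


def invert_apparent_fret(e_app: float, s: float) -> float:
    """Per-chain FRET that produces ``e_app`` at matched stall ratio ``s``.

    Inverse of :func:`apparent_fret_oracle` on the matched diagonal:
    E_chain = E_app * (1 + s).  Raises
    :class:`~nascentfret.errors.InfeasibleInversionError` when the
    required per-chain FRET would exceed 1, reporting the maximum
    feasible stall ratio.
    """
    if s < 0:
        raise ValueError("stall ratio must be >= 0")
    if not 0.0 <= e_app <= 1.0:
        raise ValueError(f"e_app must be in [0, 1], got {e_app}")
    e_chain = e_app * (1.0 + s)
    if e_chain > 1.0:
        max_s = (1.0 / e_app) - 1.0 if e_app > 0 else np.inf
        raise InfeasibleInversionError(e_app, s, max_s)
    return e_chain


# ---------------------------------------------------------------------------
# Spectra

#: CFP emission line shape: two-Gaussian mixture, main peak 476 nm
#: (sigma 12 nm) with a 503 nm shoulder (relative amplitude 0.85,
#: sigma 18 nm), normalized to unit peak on the measurement grid.  The
#: exact shape cancels in the FRET ratio; it only needs a realistic
#: ~475-480 nm maximum for the top-five-peak averaging rule.
_LINE_MAIN_NM = 476.0
_LINE_MAIN_SIGMA = 12.0
_LINE_SHOULDER_NM = 503.0
_LINE_SHOULDER_AMP = 0.85
_LINE_SHOULDER_SIGMA = 18.0


def cfp_line_shape(wavelength: Optional[np.ndarray] = None) -> np.ndarray:
    """Unit-peak CFP emission line shape on the 450-600 nm grid."""
    wl = wavelength_grid() if wavelength is None else np.asarray(wavelength, float)
    shape = np.exp(-((wl - _LINE_MAIN_NM) ** 2) / (2 * _LINE_MAIN_SIGMA**2))
    shape = shape + _LINE_SHOULDER_AMP * np.exp(
        -((wl - _LINE_SHOULDER_NM) ** 2) / (2 * _LINE_SHOULDER_SIGMA**2)
    )
    return shape / shape.max()


def _fluorescent_signal_nm(
    params: GenerativeParams, role: str, e_chain: float
) -> float:
    """Effective fluorescent-chain concentration (nM donor equivalents)."""
    if role == "D":
        return params.rnc_conc * (1.0 + params.s_d)
    if role == "DA":
        return params.rnc_conc * ((1.0 - e_chain) + params.s_da)
    if role in ("BD", "BDA"):
        return 0.0
    raise ValueError(f"unknown role {role!r}")


def simulate_spectrum(
    params: GenerativeParams,
    role: str,
    e_chain: float,
    temperature: float = REFERENCE_TEMPERATURE,
    rng: Optional[np.random.Generator] = None,
) -> SpectrumRecord:
    """One emission scan for a reaction of the given role.

    intensity(lambda) = brightness(T) * signal_nM * S(lambda) + bg_level
    plus per-wavelength Gaussian noise with sd = noise_cv * clean value.
    """
    wl = wavelength_grid()
    signal = _fluorescent_signal_nm(params, role, e_chain)
    clean = params.brightness_at(temperature) * signal * cfp_line_shape(wl)
    clean = clean + params.bg_level
    if params.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng()
        clean = clean + rng.normal(0.0, params.noise_cv * np.abs(clean))
    return SpectrumRecord(wavelength=wl, intensity=clean, temperature=temperature)


# ---------------------------------------------------------------------------
# Counts


def expected_cpm(params: GenerativeParams, role: str) -> float:
    """Expected scintillation count rate for a role.

    D/DA reactions count CE * SA * vol * [RNC] above background; blanks
    count background only — stalled chains terminate before the amber
    codon, so the label (delivered by the suppressor tRNA) marks only
    readthrough chains.
    """
    if role in ("D", "DA"):
        return params.ce * params.sa * params.vol * params.rnc_conc + params.cpm_background
    if role in ("BD", "BDA"):
        return params.cpm_background
    raise ValueError(f"unknown role {role!r}")


def simulate_counts(
    params: GenerativeParams,
    role: str,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Realized cpm: Poisson around the expectation, or exact if disabled."""
    mean = expected_cpm(params, role)
    if not params.poisson_counts:
        return mean
    if rng is None:
        rng = np.random.default_rng()
    return float(rng.poisson(mean))


# ---------------------------------------------------------------------------
# Reaction sets and series


def _condition_rng(
    key: ConditionKey, seed: int, replicate: int
) -> np.random.Generator:
    """Independent, reproducible substream per (seed, condition, replicate)."""
    ss = np.random.SeedSequence([int(seed), key.entropy(), int(replicate)])
    return np.random.default_rng(ss)


def simulate_reaction_set(
    key: ConditionKey,
    truth: GroundTruthTable,
    seed: int,
    replicate: int = 0,
    params: Optional[GenerativeParams] = None,
    e_chain: Optional[float] = None,
) -> ReactionSet:
    """Simulate one matched D/DA/BD/BDA quadruple for a condition.

    The per-chain FRET is obtained by inverting the condition's target
    apparent FRET at the DA-reaction stall ratio, so that with matched
    stalls the measurement pipeline recovers the target exactly in the
    noise-free limit.  Pass ``e_chain`` to bypass the table (used by the
    oracle-equivalence and stall-bias property suites).

    Seeding is deterministic per (seed, condition, replicate): the same
    triple always yields a bit-identical reaction set, and distinct
    triples use independent substreams.
    """
    if params is None:
        params = GenerativeParams()
    if e_chain is None:
        e_app = truth.e_app(key)  # raises MissingConditionError if absent
        e_chain = invert_apparent_fret(e_app, params.s_da)
    rng = _condition_rng(key, seed, replicate)
    samples = {}
    for role in ROLES:
        spectrum = simulate_spectrum(
            params, role, e_chain, temperature=key.temperature, rng=rng
        )
        cpm = simulate_counts(params, role, rng=rng)
        samples[role] = ReactionSample(
            sample_id=f"{key.label()}_r{replicate}_{role}",
            role=role,
            condition=key,
            spectrum=spectrum,
            cpm=cpm,
            readthrough_ratio=params.readthrough_ratio,
            ce=params.ce,
            sa=params.sa,
            vol=params.vol,
        )
    return ExperimentBundle(
        experiment_id=f"{key.label()}_r{replicate}",
        samples=samples,
        provenance="simulated",
    )


def simulate_experiment_series(
    key: ConditionKey,
    truth: GroundTruthTable,
    n: int,
    seed: int,
    params: Optional[GenerativeParams] = None,
) -> List[ReactionSet]:
    """``n`` independent replicate quadruples for one condition."""
    if n < 1:
        raise ValueError("need at least one replicate")
    return [
        simulate_reaction_set(key, truth, seed, replicate=i, params=params)
        for i in range(n)
    ]


def simulate_thermal_series(
    key: ConditionKey,
    truth: GroundTruthTable,
    temperatures: Sequence[float],
    seed: int = 0,
    replicate: int = 0,
    params: Optional[GenerativeParams] = None,
) -> List[ReactionSet]:
    """One reaction set per temperature of a thermal scan.

    Donor brightness falls with temperature in D and DA alike (so the
    brightness change cancels in the FRET ratio, the behavior of the
    Thr389 tether control); the target apparent FRET follows the
    condition's denaturation curve in the ground-truth table.
    """
    out = []
    for t in temperatures:
        if not TEMP_MIN <= t <= TEMP_MAX:
            raise ValueError(f"temperature {t} outside [{TEMP_MIN}, {TEMP_MAX}] C")
        out.append(
            simulate_reaction_set(
                key.at_temperature(t), truth, seed, replicate=replicate,
                params=params,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Immunoblot tables

#: Reference lane intensities for the blot simulator (arbitrary
#: densitometry units): wild-type mature band C, core-glycosylated band
#: B, and the actin loading control.
_BLOT_WT_BANDC = 700.0
_BLOT_BANDB = 300.0
_BLOT_LOADING = 1000.0


def simulate_blot_table(
    relative_bandc: Mapping[str, float] = REFERENCE_BANDC_FRACTIONS,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Immunoblot lane intensities for the requested constructs.

    ``relative_bandc`` maps construct label -> mature band C level as a
    fraction of wild type (loading-normalized).  Each replicate lane gets
    independent multiplicative Gaussian noise of CV ``noise_cv`` per band.

    Returns a tidy frame with columns construct, replicate, band_B,
    band_C, loading_control.
    """
    for label, frac in relative_bandc.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(
                f"relative band C fraction for {label!r} must be in [0,1]"
            )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB107]))
    rows = []
    for label, frac in relative_bandc.items():
        for rep in range(n_replicates):
            band_c = _BLOT_WT_BANDC * frac
            band_b = _BLOT_BANDB
            loading = _BLOT_LOADING
            if noise_cv > 0:
                band_c = max(band_c * (1 + rng.normal(0, noise_cv)), 0.0)
                band_b = max(band_b * (1 + rng.normal(0, noise_cv)), 0.0)
                loading = max(loading * (1 + rng.normal(0, noise_cv)), 1e-9)
            rows.append(
                {
                    "construct": label,
                    "replicate": rep,
                    "band_B": band_b,
                    "band_C": band_c,
                    "loading_control": loading,
                }
            )
    return pd.DataFrame(rows)
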
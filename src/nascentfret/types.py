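"""Domain containers for the nascent-chain FRET assay.

The experiment under study measures compaction of CFTR NBD1 nascent
polypeptides stalled on the ribosome.  Each measurement is a *matched
quadruple* of cell-free translation reactions:

* ``D``   — donor only: CFP-NBD1 with an unlabeled lysine read through the
  internal amber codon; carries the |14C| label.
* ``DA``  — donor + acceptor: same construct, the amber codon suppressed
  with an acceptor-dye-carrying lysine; carries the |14C| label.
* ``BD`` / ``BDA`` — blanks: a non-fluorescent CFP variant translated with
  the same two suppressor tRNAs; contribute background fluorescence and
  background counts only.

FRET efficiency is computed by donor quenching, E = 1 - F_DA / F_D, where
F is the net blank-corrected peak fluorescence per nM nascent chain and
the concentration comes from scintillation counting of the |14C| label.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import IncompleteQuadrupleError, SpectrumGridError

#: Emission wavelength grid: 450-600 nm inclusive at 1 nm steps.
WAVELENGTH_MIN = 450
WAVELENGTH_MAX = 600
N_WAVELENGTHS = WAVELENGTH_MAX - WAVELENGTH_MIN + 1  # 151

#: The four reaction roles of a matched quadruple.
ROLES = ("D", "DA", "BD", "BDA")

#: Acceptor-dye incorporation sites used in the assay (CFTR residues).
PROBE_SITES = (389, 487, 567)

#: Assay temperature range for thermal scans, degrees C.
TEMP_MIN = 4.0
TEMP_MAX = 50.0

#: Mutation content of each construct label.  The "+PT" constructs carry
#: the S492P/I539T second-site suppressor pair on top of the CF mutation.
CONSTRUCT_MUTATIONS: Mapping[str, frozenset] = {
    "WT": frozenset(),
    "A455E": frozenset({"A455E"}),
    "L558S": frozenset({"L558S"}),
    "M470V": frozenset({"M470V"}),
    "G551D": frozenset({"G551D"}),
    "A455E+PT": frozenset({"A455E", "S492P", "I539T"}),
    "L558S+PT": frozenset({"L558S", "S492P", "I539T"}),
}


def wavelength_grid() -> np.ndarray:
    """The canonical integer emission grid, 450..600 nm."""
    return np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1, dtype=np.int64)


@dataclass(frozen=True)
class ConditionKey:
    """Identity of one assay condition.

    Parameters
    ----------
    construct_label
        Construct name (``WT``, ``A455E``, ``L558S``, ``A455E+PT``, ...).
    probe_site
        CFTR residue carrying the acceptor dye (389, 487 or 567).
    truncation
        CFTR residue at which the nascent chain ends.
    ribosome_state
        ``bound`` (peptidyl-tRNA anchored) or ``released`` (RNase A).
    temperature
        Acquisition temperature in degrees C (default 25).
    mutations
        Residue substitutions carried by the construct; derived from
        ``construct_label`` when omitted.
    """

    construct_label: str
    probe_site: int
    truncation: int
    ribosome_state: str = "bound"
    temperature: float = 25.0
    mutations: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mutations is None:
            try:
                muts = CONSTRUCT_MUTATIONS[self.construct_label]
            except KeyError:
                raise ValueError(
                    f"unknown construct {self.construct_label!r}; pass "
                    "mutations explicitly for custom constructs"
                ) from None
            object.__setattr__(self, "mutations", muts)
        else:
            object.__setattr__(self, "mutations", frozenset(self.mutations))
        if self.probe_site not in PROBE_SITES:
            raise ValueError(
                f"probe_site must be one of {PROBE_SITES}, got {self.probe_site}"
            )
        if not self.probe_site < self.truncation:
            raise ValueError(
                f"probe_site ({self.probe_site}) must precede the truncation "
                f"({self.truncation})"
            )
        if self.ribosome_state not in ("bound", "released"):
            raise ValueError(
                f"ribosome_state must be 'bound' or 'released', got "
                f"{self.ribosome_state!r}"
            )
        if not (TEMP_MIN <= self.temperature <= TEMP_MAX):
            raise ValueError(
                f"temperature {self.temperature} outside assay range "
                f"[{TEMP_MIN}, {TEMP_MAX}] C"
            )

    def label(self) -> str:
        """Stable human-readable identifier, also used for seed derivation."""
        return (
            f"{self.construct_label}_p{self.probe_site}_t{self.truncation}"
            f"_{self.ribosome_state}_T{self.temperature:g}"
        )

    def entropy(self) -> int:
        """Deterministic 31-bit stream identifier for this condition."""
        return zlib.crc32(self.label().encode("utf-8")) & 0x7FFF_FFFF

    def at_temperature(self, temperature: float) -> "ConditionKey":
        return dataclasses.replace(self, temperature=float(temperature))

    def base_key(self) -> Tuple[str, int, int, str]:
        """Temperature-free lookup key (construct, probe, truncation, state)."""
        return (
            self.construct_label,
            self.probe_site,
            self.truncation,
            self.ribosome_state,
        )


@dataclass(frozen=True)
class SpectrumRecord:
    """One CFP emission scan (lambda_ex 430 nm, lambda_em 450-600 nm)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    temperature: float = 25.0

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=np.int64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", inten)
        self.validate()

    def validate(self) -> None:
        if self.wavelength.shape != self.intensity.shape:
            raise SpectrumGridError(
                "wavelength and intensity arrays differ in length "
                f"({self.wavelength.size} vs {self.intensity.size})"
            )
        if self.wavelength.size != N_WAVELENGTHS:
            raise SpectrumGridError(
                f"expected {N_WAVELENGTHS} points (450-600 nm at 1 nm), got "
                f"{self.wavelength.size}"
            )
        if not np.array_equal(self.wavelength, wavelength_grid()):
            raise SpectrumGridError(
                "wavelengths must be the complete strictly-increasing "
                "450-600 nm integer grid"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumGridError("non-finite intensity values")


@dataclass(frozen=True)
class ReactionSample:
    """Observables of one translation reaction.

    ``cpm`` is the raw scintillation count rate; ``ce`` (counting
    efficiency), ``sa`` (specific activity of the labeled lysine,
    dpm/pmol) and ``vol`` (counted volume, ml) convert net counts to nM
    nascent chain.
    """

    sample_id: str
    role: str
    condition: ConditionKey
    spectrum: SpectrumRecord
    cpm: float
    readthrough_ratio: float
    ce: float = 0.95
    sa: float = 300.0
    vol: float = 0.5

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not np.isfinite(self.cpm) or self.cpm < 0:
            raise ValueError(f"cpm must be finite and >= 0, got {self.cpm}")
        if not 0 < self.ce <= 1:
            raise ValueError(f"counting efficiency must be in (0, 1], got {self.ce}")
        if self.sa <= 0 or self.vol <= 0:
            raise ValueError("specific activity and volume must be positive")
        if self.readthrough_ratio <= 0:
            raise ValueError("readthrough ratio must be positive")


@dataclass(frozen=True)
class ExperimentBundle:
    """A matched four-reaction experiment (one D/DA/BD/BDA quadruple)."""

    experiment_id: str
    samples: Mapping[str, ReactionSample]
    provenance: str = "simulated"
    schema_version: str = "nascent-fret/1"

    def __post_init__(self):
        missing = [r for r in ROLES if r not in self.samples]
        if missing:
            raise IncompleteQuadrupleError(missing)
        conditions = {s.condition for s in self.samples.values()}
        if len(conditions) != 1:
            raise ValueError(
                "all four samples of a bundle must share one condition"
            )
        if self.provenance not in ("simulated", "imported"):
            raise ValueError(
                f"provenance must be 'simulated' or 'imported', got "
                f"{self.provenance!r}"
            )
        object.__setattr__(self, "samples", dict(self.samples))

    @property
    def condition(self) -> ConditionKey:
        return self.samples["D"].condition

    @property
    def readthrough_ratio(self) -> float:
        return self.samples["D"].readthrough_ratio

    def __getitem__(self, role: str) -> ReactionSample:
        return self.samples[role]


#: A matched quadruple; synonym used on the simulation side.
ReactionSet = ExperimentBundle


@dataclass(frozen=True)
class PeakIntensity:
    """Mean of the five highest emission intensities (~475 nm region)."""

    value: float
    wavelengths_used: Tuple[int, ...]

    def __post_init__(self):
        if len(self.wavelengths_used) != 5:
            raise ValueError("exactly five wavelengths contribute to a peak")


@dataclass(frozen=True)
class RncConcentration:
    """Nascent-chain concentration from scintillation counting.

    value = (cpm_S - cpm_B) / (CE * SA * vol), in nM.
    """

    value: float
    cpm_s: float
    cpm_b: float
    ce: float
    sa: float
    vol: float
    flagged: bool = False


@dataclass(frozen=True)
class FretResult:
    """FRET efficiency of one matched-quadruple experiment.

    ``e_fret`` = 1 - f_da / f_d, with f_d and f_da the blank-corrected
    peak intensities per nM.  Negative values are reported as-is (noise),
    never clipped.  ``qc_pass`` reflects the D/DA readthrough-ratio band.
    """

    experiment_id: str
    condition: ConditionKey
    e_fret: float
    f_d: float
    f_da: float
    conc_d: float
    conc_da: float
    readthrough_ratio: float
    qc_pass: bool
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class ConditionProfile:
    """Replicate FRET efficiencies for one condition: mean +/- SEM, n."""

    condition: ConditionKey
    replicate_e: Tuple[float, ...]
    mean: float
    sem: float
    n: int
    n_excluded: int = 0
    low_n: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    """A two-sample Student's t comparison of two condition profiles."""

    difference_of_means: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    tail: str
    group_ns: Tuple[int, int]
    paired: bool = False
    welch: bool = False


@dataclass(frozen=True)
class ExposedLength:
    """Cytosolically exposed residue span of a nascent chain.

    The ribosome exit tunnel sequesters roughly the last 30-40 residues,
    so a bound chain truncated at residue L exposes residues up to
    ``L - tunnel_offset``; a released chain exposes up to ``L``.
    """

    truncation: int
    ribosome_state: str
    tunnel_offset: int

    @property
    def exposed_up_to(self) -> int:
        if self.ribosome_state == "bound":
            return self.truncation - self.tunnel_offset
        return self.truncation


@dataclass(frozen=True)
class FoldingWindow:
    """Contiguous truncation span with significant mutant de-compaction."""

    probe_site: Optional[int]
    start_truncation: Optional[int]
    end_truncation: Optional[int]
    truncations: Tuple[int, ...]

    @property
    def empty(self) -> bool:
        return not self.truncations


@dataclass(frozen=True)
class DeltaCurve:
    """Per-temperature wild-type-minus-mutant FRET difference curve."""

    temperatures: Tuple[float, ...]
    delta_mean: Tuple[float, ...]
    delta_sem: Tuple[float, ...]
    p_one_tailed: Tuple[float, ...]


@dataclass(frozen=True)
class BlotLane:
    """One immunoblot lane: band B (core-glycosylated), band C (mature)."""

    construct_label: str
    band_b: float
    band_c: float
    loading_control: float

    def __post_init__(self):
        if self.band_b < 0 or self.band_c < 0:
            raise ValueError("band intensities must be >= 0")
        if self.loading_control <= 0:
            raise ValueError("loading control intensity must be positive")


@dataclass(frozen=True)
class MaturationResult:
    """Mutant trafficking expressed relative to wild type.

    ``relative_to_wt`` is the loading-normalized band-C ratio, in percent
    of wild type.
    """

    construct_label: str
    relative_to_wt: float
    sem: float
    n: int
    replicate_values: Tuple[float, ...]
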
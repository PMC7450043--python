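"""End-to-end orchestration: scenario -> simulate -> analyze -> report.

A *scenario* (JSON or YAML) declares which assay conditions to simulate,
how many replicates, the noise settings and the master seed; the
pipeline simulates the matched quadruples, runs the FRET measurement on
each, aggregates condition profiles, and executes whichever analyses the
scenario requests (length scans with folding-window detection, thermal
scans with difference curves, blot-based maturation).  Every run writes
a manifest with content hashes so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .analysis import (
    DEFAULT_ALPHA,
    aggregate_profile,
    delta_fret,
    detect_folding_window,
    length_scan,
    thermal_curve,
)
from .core import compute_experiment_fret
from .errors import ScenarioError
from .fixtures import (
    GroundTruthTable,
    LENGTH_SCAN_TRUNCATIONS,
    REFERENCE_BANDC_FRACTIONS,
    reference_truth_table,
)
from .io import SCHEMA_VERSION, results_table, write_bundle, write_results
from .maturation import lanes_from_table, relative_trafficking
from .synthetic import (
    GenerativeParams,
    simulate_blot_table,
    simulate_experiment_series,
)
from .types import ConditionKey, ConditionProfile, FretResult

__all__ = [
    "Scenario",
    "load_scenario",
    "reference_scenario",
    "run_pipeline",
    "profiles_from_results",
]


@dataclass
class Scenario:
    """Declarative description of one pipeline run."""

    seed: int
    n_replicates: int = 4
    noise_cv: float = 0.02
    poisson_counts: bool = True
    stall_ratio: float = 0.1
    alpha: float = DEFAULT_ALPHA
    keep_qc_failed: bool = False
    write_bundles: bool = False
    #: extra single conditions: dicts with construct/probe_site/truncation/...
    conditions: List[dict] = field(default_factory=list)
    #: length scans: dicts with mutant, probe_site, truncations
    length_scans: List[dict] = field(default_factory=list)
    #: thermal scans: dicts with mutant, probe_site, truncation, temperatures
    thermal_scans: List[dict] = field(default_factory=list)
    #: construct -> band-C fraction of wild type; None disables the stage
    maturation_fractions: Optional[Dict[str, float]] = None

    def validate(self) -> None:
        if self.seed is None:
            raise ScenarioError("a seed is required for simulation runs")
        if self.n_replicates < 1:
            raise ScenarioError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ScenarioError("noise_cv must be >= 0")
        if not 0 < self.alpha < 1:
            raise ScenarioError("alpha must be in (0, 1)")
        if not (self.conditions or self.length_scans or self.thermal_scans
                or self.maturation_fractions):
            raise ScenarioError("scenario declares no work")

    def params(self) -> GenerativeParams:
        return GenerativeParams(
            s_d=self.stall_ratio,
            s_da=self.stall_ratio,
            noise_cv=self.noise_cv,
            poisson_counts=self.poisson_counts,
        )


def _key_from_dict(d: Mapping, temperature: float = 25.0) -> ConditionKey:
    return ConditionKey(
        construct_label=str(d["construct"]),
        probe_site=int(d["probe_site"]),
        truncation=int(d["truncation"]),
        ribosome_state=str(d.get("ribosome_state", "bound")),
        temperature=float(d.get("temperature", temperature)),
    )


def load_scenario(path) -> Scenario:
    """Load a scenario from a JSON or YAML file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ScenarioError(f"scenario file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(data) - known
    if unknown:
        raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
    if "seed" not in data:
        raise ScenarioError("a seed is required for simulation runs")
    scenario = Scenario(**data)
    scenario.validate()
    return scenario


def reference_scenario(seed: int = 1) -> Scenario:
    """The packaged study-replication scenario.

    Length scans for A455E and L558S against wild type over the full
    truncation series (acceptor at Arg487), thermal scans of the
    truncation-654 intermediate, the suppressor-rescue condition, and
    the trafficking blot fixture.
    """
    return Scenario(
        seed=seed,
        n_replicates=4,
        conditions=[
            {"construct": "A455E+PT", "probe_site": 487, "truncation": 654},
        ],
        length_scans=[
            {"mutant": "A455E", "probe_site": 487,
             "truncations": list(LENGTH_SCAN_TRUNCATIONS)},
            {"mutant": "L558S", "probe_site": 487,
             "truncations": list(LENGTH_SCAN_TRUNCATIONS)},
        ],
        thermal_scans=[
            {"mutant": "A455E", "probe_site": 487, "truncation": 654,
             "temperatures": [4, 15, 25, 35, 45, 50]},
            {"mutant": "L558S", "probe_site": 487, "truncation": 654,
             "temperatures": [4, 15, 25, 35, 45, 50]},
        ],
        maturation_fractions=dict(REFERENCE_BANDC_FRACTIONS),
    )


def profiles_from_results(
    df: pd.DataFrame, keep_qc_failed: bool = False
) -> Dict[Tuple, ConditionProfile]:
    """Group a results table into per-condition profiles.

    Keys are (construct, probe_site, truncation, ribosome_state,
    temperature).  QC-failed replicates are excluded unless requested.
    """
    profiles: Dict[Tuple, ConditionProfile] = {}
    group_cols = ["construct", "probe_site", "truncation", "ribosome_state",
                  "temperature"]
    for key, sub in df.groupby(group_cols):
        results = [
            FretResult(
                experiment_id=str(row["experiment_id"]),
                condition=ConditionKey(
                    construct_label=key[0], probe_site=int(key[1]),
                    truncation=int(key[2]), ribosome_state=key[3],
                    temperature=float(key[4]),
                ),
                e_fret=float(row["e_fret"]),
                f_d=float(row["f_d"]),
                f_da=float(row["f_da"]),
                conc_d=float(row["conc_d"]),
                conc_da=float(row["conc_da"]),
                readthrough_ratio=float(row["readthrough_ratio"]),
                qc_pass=bool(row["qc_pass"]),
            )
            for _, row in sub.iterrows()
        ]
        profiles[key] = aggregate_profile(results, include_qc_failed=keep_qc_failed)
    return profiles


def _profile_rows(profiles: Mapping[Tuple, ConditionProfile]) -> pd.DataFrame:
    rows = []
    for key, p in sorted(profiles.items(), key=lambda kv: tuple(map(str, kv[0]))):
        rows.append(
            {
                "construct": key[0], "probe_site": key[1], "truncation": key[2],
                "ribosome_state": key[3], "temperature": key[4],
                "mean_e_fret": p.mean, "sem": p.sem, "n": p.n,
                "n_excluded": p.n_excluded, "low_n": p.low_n,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    scenario: Scenario,
    out_dir,
    truth: Optional[GroundTruthTable] = None,
) -> Dict[str, object]:
    """Execute a scenario end to end; returns the run manifest.

    Writes into ``out_dir``: ``results.tsv`` (per-experiment FRET),
    ``profiles.tsv`` (condition means), per-scan ``scan_<mutant>.tsv``
    with ``windows.json``, thermal ``thermal_<mutant>.tsv`` and
    ``delta_<mutant>.tsv``, ``maturation.tsv``, and ``manifest.json``
    listing every output with its content hash.
    """
    scenario.validate()
    if truth is None:
        truth = reference_truth_table()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = scenario.params()

    # ---- collect every condition the scenario references
    keys: List[ConditionKey] = [_key_from_dict(d) for d in scenario.conditions]
    for scan in scenario.length_scans:
        for construct in ("WT", str(scan["mutant"])):
            for trunc in scan["truncations"]:
                keys.append(
                    ConditionKey(construct, int(scan["probe_site"]), int(trunc))
                )
    thermal_keys: List[ConditionKey] = []
    for tscan in scenario.thermal_scans:
        for construct in ("WT", str(tscan["mutant"])):
            for temp in tscan["temperatures"]:
                thermal_keys.append(
                    ConditionKey(
                        construct, int(tscan["probe_site"]),
                        int(tscan["truncation"]), temperature=float(temp),
                    )
                )
    all_keys = list(dict.fromkeys(keys + thermal_keys))
    for key in all_keys:
        if key not in truth:
            raise ScenarioError(
                f"condition {key.label()} not resolvable in the ground-truth table"
            )

    # ---- simulate + measure
    results: List[FretResult] = []
    for key in all_keys:
        bundles = simulate_experiment_series(
            key, truth, scenario.n_replicates, scenario.seed, params=params
        )
        for bundle in bundles:
            if scenario.write_bundles:
                write_bundle(bundle, out / "bundles" / bundle.experiment_id)
            results.append(compute_experiment_fret(bundle))
    df = results_table(results)
    write_results(df, out / "results.tsv", seed=scenario.seed)

    profiles = profiles_from_results(df, keep_qc_failed=scenario.keep_qc_failed)
    _profile_rows(profiles).to_csv(out / "profiles.tsv", sep="\t", index=False,
                                   float_format="%.17g")

    def prof(key: ConditionKey) -> ConditionProfile:
        return profiles[(key.construct_label, key.probe_site, key.truncation,
                         key.ribosome_state, key.temperature)]

    # ---- length scans + folding windows
    windows = {}
    for scan in scenario.length_scans:
        mutant = str(scan["mutant"])
        probe = int(scan["probe_site"])
        truncs = [int(t) for t in scan["truncations"]]
        wt_profiles = {t: prof(ConditionKey("WT", probe, t)) for t in truncs}
        mut_profiles = {t: prof(ConditionKey(mutant, probe, t)) for t in truncs}
        table = length_scan(wt_profiles, mut_profiles)
        table.to_csv(out / f"scan_{mutant}.tsv", sep="\t", index=False,
                     float_format="%.17g")
        window = detect_folding_window(table, alpha=scenario.alpha,
                                       probe_site=probe)
        windows[mutant] = {
            "probe_site": probe,
            "start_truncation": window.start_truncation,
            "end_truncation": window.end_truncation,
            "truncations": list(window.truncations),
        }
    if windows:
        (out / "windows.json").write_text(json.dumps(windows, indent=2) + "\n")

    # ---- thermal scans + difference curves
    for tscan in scenario.thermal_scans:
        mutant = str(tscan["mutant"])
        probe = int(tscan["probe_site"])
        trunc = int(tscan["truncation"])
        temps = [float(t) for t in tscan["temperatures"]]
        series = {}
        for construct in ("WT", mutant):
            series[construct] = [
                prof(ConditionKey(construct, probe, trunc, temperature=t))
                for t in sorted(temps)
            ]
        rows = []
        for construct, profs in series.items():
            for p in profs:
                rows.append(
                    {"construct": construct,
                     "temperature": p.condition.temperature,
                     "mean_e_fret": p.mean, "sem": p.sem, "n": p.n}
                )
        pd.DataFrame(rows).to_csv(out / f"thermal_{mutant}.tsv", sep="\t",
                                  index=False, float_format="%.17g")
        delta = delta_fret(series["WT"], series[mutant])
        pd.DataFrame(
            {
                "temperature": delta.temperatures,
                "delta_mean": delta.delta_mean,
                "delta_sem": delta.delta_sem,
                "p_one_tailed": delta.p_one_tailed,
            }
        ).to_csv(out / f"delta_{mutant}.tsv", sep="\t", index=False,
                 float_format="%.17g")

    # ---- maturation
    if scenario.maturation_fractions:
        blot = simulate_blot_table(
            scenario.maturation_fractions,
            noise_cv=scenario.noise_cv,
            seed=scenario.seed,
            n_replicates=scenario.n_replicates,
        )
        wt_lanes = lanes_from_table(blot, "WT")
        rows = []
        for construct in scenario.maturation_fractions:
            if construct == "WT":
                continue
            res = relative_trafficking(lanes_from_table(blot, construct), wt_lanes)
            rows.append(
                {"construct": construct, "relative_to_wt": res.relative_to_wt,
                 "sem": res.sem, "n": res.n}
            )
        pd.DataFrame(rows).to_csv(out / "maturation.tsv", sep="\t", index=False,
                                  float_format="%.17g")

    # ---- manifest
    qc_excluded = int(sum(p.n_excluded for p in profiles.values()))
    outputs = sorted(
        str(p.relative_to(out)) for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "schema": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": scenario.seed,
        "n_replicates": scenario.n_replicates,
        "noise_cv": scenario.noise_cv,
        "n_experiments": len(results),
        "n_qc_excluded": qc_excluded,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
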
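"""Plain-text serialization of experiment bundles and result tables.

A bundle directory holds one matched quadruple:

    <bundle>/
      metadata.tsv          one row per sample (role, condition fields,
                            cpm, counting constants, readthrough ratio)
      spectra/<sample>.csv  wavelength_nm,intensity (451-600 nm grid)

Results tables are TSV with a comment header carrying the schema version
and seed provenance.  Everything is diff-able text; writing the same
objects twice produces byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteQuadrupleError, SchemaVersionError, SpectrumGridError
from .types import (
    ConditionKey,
    ExperimentBundle,
    FretResult,
    N_WAVELENGTHS,
    ReactionSample,
    ROLES,
    SpectrumRecord,
)

__all__ = [
    "SCHEMA_VERSION",
    "write_bundle",
    "read_bundle",
    "results_table",
    "write_results",
    "read_results",
]

SCHEMA_VERSION = "nascent-fret/1"

_METADATA_COLUMNS = [
    "sample_id", "role", "construct", "probe_site", "truncation",
    "ribosome_state", "temperature", "readthrough_ratio", "cpm",
    "ce", "sa", "vol", "experiment_id", "provenance", "schema_version",
]

RESULT_COLUMNS = [
    "experiment_id", "construct", "probe_site", "truncation",
    "ribosome_state", "temperature", "e_fret", "qc_pass",
    "f_d", "f_da", "conc_d", "conc_da", "readthrough_ratio", "flags",
]

#: Full-precision float formatting for lossless text round trips.
_FLOAT_FMT = "%.17g"


def write_bundle(bundle: ExperimentBundle, path: os.PathLike) -> None:
    """Write one quadruple as metadata.tsv + per-sample spectrum CSVs."""
    root = Path(path)
    spectra_dir = root / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for role in ROLES:
        s = bundle[role]
        c = s.condition
        rows.append(
            {
                "sample_id": s.sample_id,
                "role": role,
                "construct": c.construct_label,
                "probe_site": c.probe_site,
                "truncation": c.truncation,
                "ribosome_state": c.ribosome_state,
                "temperature": c.temperature,
                "readthrough_ratio": s.readthrough_ratio,
                "cpm": s.cpm,
                "ce": s.ce,
                "sa": s.sa,
                "vol": s.vol,
                "experiment_id": bundle.experiment_id,
                "provenance": bundle.provenance,
                "schema_version": bundle.schema_version,
            }
        )
        spec = pd.DataFrame(
            {
                "wavelength_nm": s.spectrum.wavelength,
                "intensity": s.spectrum.intensity,
            }
        )
        spec.to_csv(
            spectra_dir / f"{s.sample_id}.csv", index=False,
            float_format=_FLOAT_FMT,
        )
    meta = pd.DataFrame(rows, columns=_METADATA_COLUMNS)
    meta.to_csv(root / "metadata.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)


def read_bundle(path: os.PathLike) -> ExperimentBundle:
    """Read and validate a bundle directory.

    Raises :class:`SchemaVersionError` on version mismatch,
    :class:`IncompleteQuadrupleError` when a role is missing, and
    :class:`SpectrumGridError` when a spectrum violates the 151-point
    450-600 nm grid.
    """
    root = Path(path)
    meta_path = root / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.tsv in {root}")
    meta = pd.read_csv(meta_path, sep="\t", float_precision="round_trip")
    versions = set(meta["schema_version"].astype(str))
    if versions != {SCHEMA_VERSION}:
        raise SchemaVersionError(
            f"unsupported schema version(s) {sorted(versions)}; this reader "
            f"understands {SCHEMA_VERSION}"
        )
    present = set(meta["role"])
    missing = [r for r in ROLES if r not in present]
    if missing:
        raise IncompleteQuadrupleError(missing)

    samples = {}
    experiment_id = str(meta["experiment_id"].iloc[0])
    provenance = str(meta["provenance"].iloc[0])
    for _, row in meta.iterrows():
        spec_path = root / "spectra" / f"{row['sample_id']}.csv"
        if not spec_path.exists():
            raise FileNotFoundError(f"missing spectrum file {spec_path}")
        spec = pd.read_csv(spec_path, float_precision="round_trip")
        n = len(spec)
        if n != N_WAVELENGTHS:
            raise SpectrumGridError(
                f"{spec_path.name}: expected {N_WAVELENGTHS} rows "
                f"(450-600 nm at 1 nm), got {n}"
            )
        condition = ConditionKey(
            construct_label=str(row["construct"]),
            probe_site=int(row["probe_site"]),
            truncation=int(row["truncation"]),
            ribosome_state=str(row["ribosome_state"]),
            temperature=float(row["temperature"]),
        )
        spectrum = SpectrumRecord(
            wavelength=spec["wavelength_nm"].to_numpy(),
            intensity=spec["intensity"].to_numpy(),
            temperature=float(row["temperature"]),
        )
        samples[str(row["role"])] = ReactionSample(
            sample_id=str(row["sample_id"]),
            role=str(row["role"]),
            condition=condition,
            spectrum=spectrum,
            cpm=float(row["cpm"]),
            readthrough_ratio=float(row["readthrough_ratio"]),
            ce=float(row["ce"]),
            sa=float(row["sa"]),
            vol=float(row["vol"]),
        )
    return ExperimentBundle(
        experiment_id=experiment_id,
        samples=samples,
        provenance=provenance,
    )


def results_table(results: Sequence[FretResult]) -> pd.DataFrame:
    """Tidy results frame with the stable column set (may be empty)."""
    rows = []
    for r in results:
        c = r.condition
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "construct": c.construct_label,
                "probe_site": c.probe_site,
                "truncation": c.truncation,
                "ribosome_state": c.ribosome_state,
                "temperature": c.temperature,
                "e_fret": r.e_fret,
                "qc_pass": r.qc_pass,
                "f_d": r.f_d,
                "f_da": r.f_da,
                "conc_d": r.conc_d,
                "conc_da": r.conc_da,
                "readthrough_ratio": r.readthrough_ratio,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    results: pd.DataFrame, path: os.PathLike, seed: Optional[int] = None
) -> None:
    """Write a results table as TSV with a schema/seed comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing and not results.empty:
        raise ValueError(f"results table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df = results if not results.empty else pd.DataFrame(columns=RESULT_COLUMNS)
        df.to_csv(fh, sep="\t", index=False, columns=RESULT_COLUMNS,
                  float_format=_FLOAT_FMT)


def read_results(path: os.PathLike) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith(f"# schema: {SCHEMA_VERSION}"):
        raise SchemaVersionError(
            f"{path}: missing or unsupported schema header ({first.strip()!r})"
        )
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    df["flags"] = df.get("flags", pd.Series(dtype=str)).fillna("")
    return df
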
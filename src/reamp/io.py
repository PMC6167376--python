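"""Shared file I/O: FASTA, typed delimited tables, config and run records."""

from __future__ import annotations

import datetime
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import TitrationSeries
from .design import Alignment
from .hydro import MicellePoint, SECStandard
from .redox import PotentiometrySeries

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_table",
    "read_titration_csv",
    "read_potentiometry_csv",
    "read_standards_csv",
    "read_micelle_csv",
    "load_config",
    "DEFAULT_CONFIG",
    "write_run_record",
]

#: Every overridable numeric default, grouped per module section.
DEFAULT_CONFIG = {
    "design": {
        "consensus_threshold": 0.5,
        "gly_conservation_threshold": 0.5,
        "trp_position": 50,
    },
    "bundle": {
        "n_res_per_helix": 21,
        "rise_per_res": 1.5,
        "twist_deg": 100.0,
        "helix_radius": 2.3,
        "inter_axis_spacing": 10.0,
        "membrane_half_thickness": 15.75,
        "angular_cutoff_deg": 60.0,
        "depth_target": 10.0,
        "depth_tol": 4.0,
        "bridge_window": [9.0, 14.0],
        "clash_cutoff": 7.0,
    },
    "hydro": {
        "micelle_mass_kda": 22.5,
        "monomer_mass_kda": 13.8,
    },
    "bind": {
        "his_per_protomer": 2,
    },
    "redox": {
        "hysteresis_threshold_mv": 10.0,
    },
    "simulate": {
        "noise_sd": 0.0,
    },
    "log_level": "INFO",
    "output_dir": ".",
}


def read_fasta(path):
    """Read a (possibly gapped) FASTA file into [(id, sequence), ...]."""
    from Bio import SeqIO

    path = Path(path)
    if path.stat().st_size == 0:
        return []
    records = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path}: line 1: malformed FASTA (expected '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records, path, wrap=60):
    """Write [(id, sequence), ...] as FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def read_alignment(path, tm_windows):
    """Read an aligned FASTA into an :class:`~reamp.design.Alignment`."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"{path}: empty alignment")
    ids, seqs = zip(*records)
    return Alignment(list(seqs), list(ids), [tuple(w) for w in tm_windows])


def _sep_for(path):
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(path, schema):
    """Read a delimited table with a typed column schema.

    ``schema`` maps required column names to callables (e.g. ``float``).
    Missing columns and unconvertible cells raise with the offending
    column (and row) named; extra columns pass through untouched.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col, typ in schema.items():
        if typ in (float, int):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[converted.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: column {col!r}, row {bad[0] + 1}: "
                    f"non-numeric value {df.loc[bad[0], col]!r}"
                )
            df[col] = converted.astype(typ)
        else:
            df[col] = df[col].astype(typ)
    return df


def _header_metadata(path):
    """Parse ``# key: value`` comment lines from the top of a file."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_titration_csv(path):
    """Titration CSV: ``# protein_uM:`` / ``# pathlength_cm:`` header comments
    plus columns ligand_uM, signal."""
    meta = _header_metadata(path)
    if "protein_uM" not in meta:
        raise ValueError(f"{path}: header must declare '# protein_uM: <value>'")
    df = read_table(path, {"ligand_uM": float, "signal": float})
    return TitrationSeries(
        float(meta["protein_uM"]),
        df["ligand_uM"].to_numpy(),
        df["signal"].to_numpy(),
        float(meta.get("pathlength_cm", 1.0)),
    )


def read_potentiometry_csv(path):
    """Potentiometry CSV with columns eh_mV, absorbance and optional sweep."""
    df = read_table(path, {"eh_mV": float, "absorbance": float})
    sweep = str(df["sweep"].iloc[0]) if "sweep" in df.columns else "reductive"
    return PotentiometrySeries(df["eh_mV"].to_numpy(), df["absorbance"].to_numpy(),
                               sweep)


def read_standards_csv(path):
    """SEC standards CSV: name, mass_kDa, rs_nm[, s_value]."""
    df = read_table(path, {"name": str, "mass_kDa": float, "rs_nm": float})
    out = []
    for _, row in df.iterrows():
        s = row.get("s_value")
        out.append(SECStandard(row["name"], row["mass_kDa"], row["rs_nm"],
                               None if s is None or pd.isna(s) else float(s)))
    return out


def read_micelle_csv(path):
    """Micelle series CSV: detergent, micelle_mass_kDa, apparent_mass_kDa."""
    df = read_table(path, {"micelle_mass_kDa": float, "apparent_mass_kDa": float})
    return [
        MicellePoint(row["micelle_mass_kDa"], row["apparent_mass_kDa"],
                     str(row.get("detergent", "")))
        for _, row in df.iterrows()
    ]


def _merge(base, override, path=""):
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {path + key!r} must be a mapping")
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path=None):
    """Load a YAML config, validated and merged over the package defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def write_run_record(command, config, input_paths, out_dir):
    """Write a provenance record (command, config, input checksums) as JSON."""
    from . import __version__

    checksums = {}
    for p in input_paths:
        p = Path(p)
        checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    record = {
        "command": command,
        "config": config,
        "input_sha256": checksums,
        "versions": {"reamp": __version__, "python": sys.version.split()[0],
                     "numpy": np.__version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / "run_record.json"
    out_path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return out_path
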
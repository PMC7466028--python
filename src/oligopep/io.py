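"""Readers, writers, run configuration and the end-to-end report.

All tables are plain CSV/TSV with fixed headers; temperatures are Celsius at
the I/O boundary and Kelvin internally, masses in Da, energies in kcal/mol.
Errors name the offending column and row.  Reports are JSON and embed the
resolved configuration plus its hash, so identical inputs and seed reproduce
identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import cdspec, digestor, dscfit, massbook
from .errors import ConfigError, DataFormatError

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(required)} (got {','.join(df.columns)})"
        )
    if len(df) == 0:
        raise DataFormatError(f"{path}: no data rows")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if df[col].dtype == object:
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based + header line
                raise DataFormatError(
                    f"{path}: non-numeric value in column {col!r} at line {row}"
                )
        df[col] = coerced
    return df


def read_peaks_csv(path: str | Path, label: str = "") -> digestor.PeakList:
    """Peak list CSV with header ``mz,area[,rt]``."""
    df = _read_csv(path, ("mz", "area"))
    rt = df["rt"].to_numpy(float) if "rt" in df.columns else None
    return digestor.PeakList(
        mz=df["mz"].to_numpy(float),
        area=df["area"].to_numpy(float),
        rt=rt,
        label=label,
    )


def read_thermogram_csv(path: str | Path, label: str = "") -> dscfit.Thermogram:
    """Thermogram CSV: ``temp_C,cp`` or ``temp_K,cp_molar`` -> Kelvin internally."""
    path = Path(path)
    head = pd.read_csv(path, nrows=0).columns if path.exists() else []
    if "temp_K" in head:
        df = _read_csv(path, ("temp_K", "cp_molar"))
        temp = df["temp_K"].to_numpy(float)
        cp = df["cp_molar"].to_numpy(float)
    else:
        df = _read_csv(path, ("temp_C", "cp"))
        temp = dscfit.celsius_to_kelvin(df["temp_C"].to_numpy(float))
        cp = df["cp"].to_numpy(float)
    return dscfit.Thermogram(temperature=temp, cp=cp, label=label)


def read_melt_csv(path: str | Path) -> dict[str, cdspec.MeltTrace]:
    """CD melt CSV ``temp_C,ellipticity,direction`` -> traces by direction."""
    df = _read_csv(path, ("temp_C", "ellipticity"))
    if "direction" not in df.columns:
        df["direction"] = "heating"
    out: dict[str, cdspec.MeltTrace] = {}
    for direction, grp in df.groupby("direction"):
        if direction not in ("heating", "cooling"):
            raise DataFormatError(
                f"{path}: unknown direction {direction!r} "
                "(expected heating/cooling)"
            )
        out[str(direction)] = cdspec.MeltTrace(
            temperature=grp["temp_C"].to_numpy(float),
            ellipticity=grp["ellipticity"].to_numpy(float),
            direction=direction,
        )
    return out


def read_cd_spectra_csv(
    path: str | Path, concentration: float | None = None, label: str = ""
) -> dict[float, cdspec.CDSpectrum]:
    """Long-format CD CSV ``wavelength_nm,temp_C,ellipticity`` -> per-T spectra."""
    df = _read_csv(path, ("wavelength_nm", "temp_C", "ellipticity"))
    out: dict[float, cdspec.CDSpectrum] = {}
    for temp, grp in df.groupby("temp_C"):
        grp = grp.sort_values("wavelength_nm")
        out[float(temp)] = cdspec.CDSpectrum(
            wavelength=grp["wavelength_nm"].to_numpy(float),
            ellipticity=grp["ellipticity"].to_numpy(float),
            temperature=float(temp),
            label=label,
            concentration=concentration,
        )
    return out


# ---------------------------------------------------------------------------
# Sequence specifications (JSON/YAML document, or FASTA plus sidecar)
# ---------------------------------------------------------------------------

def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"input file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _oligo_from_dict(d: dict) -> massbook.ModifiedOligo:
    return massbook.ModifiedOligo(
        id=d["id"],
        sequence=d["sequence"],
        five_prime=d.get("five_prime", "OH"),
        three_prime=d.get("three_prime", "OH"),
        modifications=tuple((int(p), m) for p, m in d.get("modifications", [])),
    )


def _peptide_from_dict(d: dict) -> massbook.ModifiedPeptide:
    return massbook.ModifiedPeptide(
        id=d["id"],
        residues=tuple(d["residues"]),
        n_term=d.get("n_term", "H"),
        c_term=d.get("c_term", "OH"),
        modifications=tuple((int(p), m) for p, m in d.get("modifications", [])),
    )


def read_molecules(path: str | Path) -> dict[str, Any]:
    """Read a JSON/YAML molecule document.

    Schema: ``{"oligos": [...], "peptides": [...], "conjugates":
    [{"oligo": id, "peptide": id, "attachment_position": n}]}``.
    """
    doc = _load_structured(path)
    oligos = {d["id"]: _oligo_from_dict(d) for d in doc.get("oligos", [])}
    peptides = {d["id"]: _peptide_from_dict(d) for d in doc.get("peptides", [])}
    conjugates = {}
    for d in doc.get("conjugates", []):
        oligo = oligos.get(d["oligo"])
        peptide = peptides.get(d["peptide"])
        cid = d.get("id", f"{d['oligo']}-{d['peptide']}")
        conjugates[cid] = massbook.ConjugateSpec(
            oligo, peptide, d.get("attachment_position")
        )
    return {"oligos": oligos, "peptides": peptides, "conjugates": conjugates}


def read_fasta_with_sidecar(
    fasta_path: str | Path, sidecar_path: str | Path
) -> dict[str, massbook.ModifiedOligo]:
    """FASTA sequences with inline placeholder letters resolved by a sidecar.

    The sidecar (JSON/YAML) maps record ids to placeholder definitions:
    ``{"ssDNA A*": {"X": {"base": "C", "modification": "C8-alkyne-dC"}}}``.
    Placeholder letters in the FASTA sequence are replaced by their base and
    the modification is registered at that position.
    """
    from Bio import SeqIO

    sidecar = _load_structured(sidecar_path)
    out: dict[str, massbook.ModifiedOligo] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        rules = sidecar.get(rec.id, sidecar.get(rec.description, {}))
        bases = []
        mods: list[tuple[int, str]] = []
        for i, ch in enumerate(seq, start=1):
            if ch in "ACGT":
                bases.append(ch)
            elif ch in rules:
                bases.append(rules[ch]["base"])
                mods.append((i, rules[ch]["modification"]))
            else:
                raise DataFormatError(
                    f"{fasta_path}: record {rec.id!r} position {i}: "
                    f"letter {ch!r} is not ACGT and has no sidecar rule"
                )
        out[rec.id] = massbook.ModifiedOligo(
            id=rec.id, sequence="".join(bases), modifications=tuple(mods)
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration (strict schema) and the end-to-end report
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MassStage(_Strict):
    molecules: str  # path to molecule document
    scale: Literal["average", "monoisotopic"] = "average"
    charges: list[int] = [1, 2, 3, 4, 5, 6]


class DscStage(_Strict):
    free: str  # thermogram CSV
    bound: Optional[str] = None
    window_half_width: float = 12.0
    components_free: int = 2
    components_bound: int = 3
    t_ref_c: float = 24.85  # 298 K


class CdStage(_Strict):
    melt: str  # melt CSV with heating/cooling rows
    window: int = 5
    tol_c: float = 1.5
    wavelength: float = 220.0


class FootprintStage(_Strict):
    free_peaks: str
    bound_peaks: str
    parent: Literal["ssDNA A", "ssDNA A*", "ssDNA A**", "ssDNA B"] = "ssDNA A"
    tol_ppm: float = 25.0
    z_max: int = 6
    threshold: float = -1.0
    min_run: int = 3


class RunConfig(_Strict):
    """Strict end-to-end run configuration (unknown keys rejected)."""

    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    mass: Optional[MassStage] = None
    dsc: Optional[DscStage] = None
    cd: Optional[CdStage] = None
    footprint: Optional[FootprintStage] = None


def load_run_config(path: str | Path) -> RunConfig:
    doc = _load_structured(path)
    try:
        return RunConfig(**doc)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from None


_PARENTS = {
    "ssDNA A": massbook.ssdna_a,
    "ssDNA A*": massbook.ssdna_a_star,
    "ssDNA A**": massbook.ssdna_a_double_star,
    "ssDNA B": massbook.ssdna_b,
}


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _mass_block(stage: MassStage) -> dict:
    mols = read_molecules(stage.molecules)
    rows = []
    for oid, oligo in mols["oligos"].items():
        m = massbook.oligo_neutral_mass(oligo, stage.scale)
        rows.append({"id": oid, "kind": "oligo", "neutral_mass": m})
    for pid, pep in mols["peptides"].items():
        m = massbook.peptide_neutral_mass(pep, stage.scale)
        rows.append({"id": pid, "kind": "peptide", "neutral_mass": m})
    for cid, conj in mols["conjugates"].items():
        m = massbook.conjugate_mass(conj, stage.scale)
        rows.append({"id": cid, "kind": "conjugate", "neutral_mass": m})
    for row in rows:
        row["mz"] = {
            str(z): mz
            for z, mz in massbook.mz_for_charges(
                row["neutral_mass"], stage.charges, scale=stage.scale
            )
        }
    return {"scale": stage.scale, "proton_mass": massbook.PROTON_MASS[stage.scale],
            "molecules": rows}


def _dsc_block(stage: DscStage) -> dict:
    t_ref = dscfit.celsius_to_kelvin(stage.t_ref_c)

    def one(path: str, k: int, label: str) -> tuple[dict, dscfit.TwoStateModel]:
        tg = read_thermogram_csv(path, label=label)
        res = dscfit.analyze_thermogram(
            tg,
            transition_window=dscfit.guess_transition_window(
                tg, stage.window_half_width
            ),
            n_gaussians=k,
            t_ref=float(t_ref),
        )
        model: dscfit.TwoStateModel = res["model"]
        th: dscfit.ThermoFunctions = res["thermo_at_ref"]
        block = {
            "t_m_c": model.t_m_celsius,
            "dh_m": model.dh_m,
            "dcp": model.dcp,
            "dh_calorimetric": res["dh_calorimetric"],
            "at_t_ref": {
                "T_K": th.temperature,
                "delta_g": th.delta_g,
                "delta_h": th.delta_h,
                "delta_s": th.delta_s,
            },
            "gaussians": [
                {"center_c": g.center - dscfit.C_TO_K, "sigma": g.sigma, "area": g.area}
                for g in res.get("gaussians", [])
            ],
        }
        return block, model

    out: dict[str, Any] = {}
    out["free"], model_free = one(stage.free, stage.components_free, "free")
    if stage.bound:
        out["bound"], model_bound = one(
            stage.bound, stage.components_bound, "bound"
        )
        out["delta_g_difference"] = dscfit.delta_g_difference(
            model_free, model_bound, float(t_ref)
        )
        out["t_m_shift_c"] = model_bound.t_m - model_free.t_m
    return out


def _cd_block(stage: CdStage) -> dict:
    traces = read_melt_csv(stage.melt)
    fits = {
        d: cdspec.tm_from_derivative(tr, stage.window) for d, tr in traces.items()
    }
    block: dict[str, Any] = {
        d: {"t_m_c": f.t_m, "no_transition": f.no_transition}
        for d, f in fits.items()
    }
    if "heating" in fits and "cooling" in fits:
        rev, dtm = cdspec.reversibility(
            fits["heating"], fits["cooling"], stage.tol_c
        )
        block["reversible"] = rev
        block["hysteresis_c"] = dtm
    return block


def _footprint_block(stage: FootprintStage) -> dict:
    parent = _PARENTS[stage.parent]()
    call = digestor.footprint(
        read_peaks_csv(stage.free_peaks, "free"),
        read_peaks_csv(stage.bound_peaks, "bound"),
        parent,
        tol_ppm=stage.tol_ppm,
        charges=tuple(range(1, stage.z_max + 1)),
        threshold=stage.threshold,
        min_run=stage.min_run,
    )
    return {
        "parent": stage.parent,
        "window": list(call.window) if call.window else None,
        "scores": [float(s) for s in call.scores],
        "threshold": call.threshold,
        "min_run": call.min_run,
    }


def run_report(config: RunConfig) -> dict:
    """Execute the requested stages and write ``report.json``.

    Any stage error aborts the whole report (no partial file is written);
    the report embeds the resolved configuration and its hash.
    """
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "results": {},
    }
    if config.mass:
        report["results"]["mass"] = _mass_block(config.mass)
    if config.dsc:
        report["results"]["dsc"] = _dsc_block(config.dsc)
    if config.cd:
        report["results"]["cd"] = _cd_block(config.cd)
    if config.footprint:
        report["results"]["footprint"] = _footprint_block(config.footprint)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Writers for per-stage artifacts
# ---------------------------------------------------------------------------

def write_assignments_tsv(
    assignments: list[digestor.Assignment], path: str | Path
) -> None:
    rows = []
    for a in assignments:
        if not a.candidates:
            rows.append(
                {"peak": a.peak_index, "mz": a.mz, "area": a.area,
                 "fragment": "", "z": "", "ppm": "", "group": ""}
            )
        for cand, gid in zip(a.candidates, a.group_ids):
            rows.append(
                {
                    "peak": a.peak_index,
                    "mz": a.mz,
                    "area": a.area,
                    "fragment": f"{cand.fragment.start}-{cand.fragment.end}",
                    "z": cand.z,
                    "ppm": round(cand.ppm_error, 3),
                    "group": gid,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: digestor.CleavageProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_protection_json(call: digestor.ProtectionCall, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "parent": call.parent_id,
                "window": list(call.window) if call.window else None,
                "scores": [float(s) for s in call.scores],
                "threshold": call.threshold,
                "min_run": call.min_run,
            },
            indent=2,
        )
    )


def write_peaks_csv(peaks: digestor.PeakList, path: str | Path) -> None:
    peaks.to_frame().to_csv(path, index=False)


def write_thermogram_csv(tg: dscfit.Thermogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "temp_C": dscfit.kelvin_to_celsius(tg.temperature),
            "cp": tg.cp,
        }
    ).to_csv(path, index=False)


def write_melt_csv(traces: list[cdspec.MeltTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "temp_C": tr.temperature,
                "ellipticity": tr.ellipticity,
                "direction": tr.direction,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
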
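"""On-disk formats: stage files, spectra matrices, cohort manifests,
metric tables.

Native formats are plain text and locale-independent:

* stage file — CSV, one epoch per row (``zt_h,state,artifact``) with a
  ``# key=value`` metadata header (``epoch_s``, ``animal_id``);
* scoring-export dialect — a tolerant reader for scoring-software-style
  exports: state tokens one per line or comma-separated, labels mapped
  case-insensitively ({W, Wake} -> WAKE, {N, NR, NREM} -> NREM,
  {R, REM} -> REM), a trailing ``*`` marking artifact epochs;
* spectra — CSV, header names the frequency grid (``f_<Hz>`` columns);
* cohort manifest — YAML listing per-animal files, metadata, and
  exclusion scope;
* metric/stat tables — CSV with fixed column order, deterministic row
  order, and NaN written as literal ``NA``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    STATE_CODES,
    STATE_LABELS,
    AnimalMeta,
    EpochSpectra,
    Hypnogram,
    Protocol,
    Recording,
)

_LABEL_MAP = {
    "W": "WAKE",
    "WAKE": "WAKE",
    "N": "NREM",
    "NR": "NREM",
    "NREM": "NREM",
    "R": "REM",
    "REM": "REM",
}

DIALECTS = ("native_csv", "scoring_export")


def _map_label(token: str, lineno: int, path) -> tuple[int, bool]:
    tok = token.strip()
    artifact = tok.endswith("*")
    tok = tok.rstrip("*").strip().upper()
    if tok not in _LABEL_MAP:
        raise ValueError(
            f"{path}: unknown state label {token.strip()!r} on line {lineno}"
        )
    return STATE_CODES[_LABEL_MAP[tok]], artifact


def read_stage_file(path, dialect: str = "native_csv",
                    epoch_s: float | None = None) -> Hypnogram:
    """Parse a stage file into a :class:`Hypnogram`.

    ``epoch_s`` overrides the header (native) or the dialect default of
    4 s (scoring export).  Unknown state labels raise a hard error naming
    the offending line.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    text = path.read_text()
    if dialect == "native_csv":
        return _read_native(path, text, epoch_s)
    return _read_scoring_export(path, text, epoch_s or 4.0)


def _read_native(path, text: str, epoch_s) -> Hypnogram:
    meta = {}
    states, artifact = [], []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for part in line.lstrip("#").split():
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k] = v
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        fields = line.split(",")
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed row on line {lineno}")
        code, star = _map_label(fields[1], lineno, path)
        states.append(code)
        art = star
        if len(fields) >= 3 and fields[2].strip() not in ("", "0", "False", "false"):
            art = True
        artifact.append(art)
    eps = epoch_s if epoch_s is not None else float(meta.get("epoch_s", 4.0))
    return Hypnogram(
        animal_id=meta.get("animal_id", path.stem),
        states=np.array(states, dtype=np.int8),
        artifact=np.array(artifact, dtype=bool),
        epoch_s=eps,
        start_zt_h=float(meta.get("start_zt_h", 0.0)),
    )


def _read_scoring_export(path, text: str, epoch_s: float) -> Hypnogram:
    states, artifact = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for token in line.split(","):
            if not token.strip():
                continue
            code, star = _map_label(token, lineno, path)
            states.append(code)
            artifact.append(star)
    return Hypnogram(
        animal_id=path.stem,
        states=np.array(states, dtype=np.int8),
        artifact=np.array(artifact, dtype=bool),
        epoch_s=epoch_s,
    )


def write_stage_file(hypnogram: Hypnogram, path) -> None:
    """Write the native one-epoch-per-row stage CSV (lossless round trip)."""
    path = Path(path)
    zt = hypnogram.epoch_start_h()
    with open(path, "w", newline="\n") as fh:
        fh.write("# somnarch-stage-v1\n")
        fh.write(
            f"# animal_id={hypnogram.animal_id} epoch_s={hypnogram.epoch_s:g} "
            f"start_zt_h={hypnogram.start_zt_h:g}\n"
        )
        fh.write("zt_h,state,artifact\n")
        for t, s, a in zip(zt, hypnogram.states, hypnogram.artifact):
            fh.write(f"{t:.6f},{STATE_LABELS[s]},{int(a)}\n")


def write_spectra_file(spectra: EpochSpectra, path) -> None:
    """Wide CSV: one epoch per row, frequency-named columns, full precision."""
    path = Path(path)
    header = ",".join(f"f_{f:.6g}" for f in spectra.freqs)
    np.savetxt(path, spectra.power, fmt="%.17g", delimiter=",",
               header=header, comments="")


def read_spectra_file(path) -> EpochSpectra:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    freqs = np.array([float(c[2:]) for c in header])
    power = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return EpochSpectra(freqs=freqs, power=power)


METRIC_SORT_KEYS = ["animal_id", "phase", "period", "state", "hour", "zt_hour", "freq_hz"]


def write_metric_table(table: pd.DataFrame, path) -> None:
    """Deterministic long-format CSV: fixed column order, sorted rows,
    UTF-8, NaN as literal ``NA``."""
    df = table.copy()
    keys = [k for k in METRIC_SORT_KEYS if k in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, index=False, na_rep="NA", float_format="%.10g",
              lineterminator="\n", encoding="utf-8")


def read_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=False)


# ---------------------------------------------------------------------------
# cohort manifests


def write_cohort(recordings, out_dir, manifest_name: str = "cohort.yaml") -> Path:
    """Write stage (+ spectra) files and the YAML manifest for a cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    animals = []
    proto = recordings[0].protocol if recordings else Protocol()
    for rec in recordings:
        stage = f"{rec.animal_id}.stage.csv"
        write_stage_file(rec.hypnogram, out_dir / stage)
        entry = {
            "id": rec.animal_id,
            "sex": rec.meta.sex,
            "genotype": rec.meta.genotype,
            "stage": stage,
            "spectra": None,
            "excluded": rec.meta.excluded,
        }
        if rec.spectra is not None:
            entry["spectra"] = f"{rec.animal_id}.spectra.csv"
            write_spectra_file(rec.spectra, out_dir / entry["spectra"])
        animals.append(entry)
    manifest = {
        "somnarch_manifest": 1,
        "epoch_s": recordings[0].hypnogram.epoch_s if recordings else 4.0,
        "protocol": {
            "baseline": list(proto.baseline),
            "sd": list(proto.sd),
            "recovery": list(proto.recovery),
        },
        "animals": animals,
    }
    mpath = out_dir / manifest_name
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def load_cohort(manifest_path) -> list[Recording]:
    """Load and validate every recording listed in a cohort manifest.

    Animals flagged ``excluded: all`` are dropped outright; animals
    flagged ``excluded: recovery`` are loaded with the flag carried on
    their metadata so downstream recovery-phase analyses can drop them
    (:func:`somnarch.core.recordings_for_phase`).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    proto_cfg = manifest.get("protocol", {})
    protocol = Protocol(
        baseline=tuple(proto_cfg.get("baseline", (0, 24))),
        sd=tuple(proto_cfg.get("sd", (24, 29))),
        recovery=tuple(proto_cfg.get("recovery", (29, 48))),
    )
    epoch_s = float(manifest.get("epoch_s", 4.0))

    seen = set()
    recordings = []
    for entry in manifest["animals"]:
        aid = entry["id"]
        if aid in seen:
            raise ValueError(f"duplicate animal id {aid!r} in manifest")
        seen.add(aid)
        excluded = str(entry.get("excluded", "none") or "none")
        if excluded in ("False", "false"):
            excluded = "none"
        if excluded in ("True", "true"):
            excluded = "all"
        meta = AnimalMeta(aid, entry["sex"], entry["genotype"], excluded=excluded)
        if excluded == "all":
            continue
        stage_path = base / entry["stage"]
        if not stage_path.exists():
            raise FileNotFoundError(f"stage file missing for {aid}: {stage_path}")
        hyp = read_stage_file(stage_path, dialect="native_csv", epoch_s=epoch_s)
        hyp.animal_id = aid
        spectra = None
        if entry.get("spectra"):
            spath = base / entry["spectra"]
            if not spath.exists():
                raise FileNotFoundError(f"spectra file missing for {aid}: {spath}")
            spectra = read_spectra_file(spath)
        recordings.append(
            Recording(hypnogram=hyp, meta=meta, spectra=spectra, protocol=protocol)
        )
    return recordings


__all__ = [
    "DIALECTS",
    "read_stage_file",
    "write_stage_file",
    "read_spectra_file",
    "write_spectra_file",
    "write_metric_table",
    "read_metric_table",
    "write_cohort",
    "load_cohort",
]
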
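"""Reading and writing reflectivity data, sequences, configs and fit reports.

Formats
-------
* plain multi-column ASCII: whitespace-delimited ``Q R dR [dQ]`` with ``#``
  comments; SLD-bearing headers always quote 1e-6 Å⁻².
* ORSO-style ``.ort`` text: a ``#``-commented YAML header (subset of the ORSO
  specification: data source, contrast, instrument, column names) followed by
  the same numeric columns.
* FASTA for protein sequences (via Biopython).
* YAML model configurations; CSV/JSON/plain-text fit reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .components import CONTRAST_ORDER, SolventContrast
from .dataset import ReflectivityDataset

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "read_sequence",
    "packaged_sequence",
    "write_results",
    "read_results",
    "setup_run_log",
]

log = logging.getLogger("refmem")

_CONTRAST_ALIASES = {c.lower(): c for c in CONTRAST_ORDER}


def normalize_contrast(name: str) -> str:
    """Case-insensitive normalization to the standard contrast labels."""
    return _CONTRAST_ALIASES.get(name.strip().lower(), name.strip())


def _parse_numeric_block(lines, path):
    rows = []
    for lineno, line in lines:
        parts = line.split()
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric row: {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != ncol)
        raise ValueError(f"{path}: inconsistent column count at data row {bad + 1}")
    return np.array(rows)


def read_reflectivity(path, format: str | None = None) -> ReflectivityDataset:
    """Read a reflectivity dataset from ``.ort`` or plain ASCII.

    Requires at least three columns (Q, R, dR); a fourth column is taken as
    per-point dQ (FWHM).  ORSO-style headers contribute contrast/instrument
    metadata.  Datasets without uncertainties are rejected with a pointer to
    the simulation facilities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("ort" if path.suffix.lower() == ".ort" else "ascii")
    header_lines, data_lines = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line.lstrip("#").strip())
            else:
                data_lines.append((lineno, line))
    meta = {}
    if fmt == "ort" and header_lines:
        try:
            parsed = yaml.safe_load("\n".join(header_lines))
            if isinstance(parsed, dict):
                meta = parsed
        except yaml.YAMLError:
            pass
    data = _parse_numeric_block(data_lines, path)
    if data.shape[1] < 3:
        raise ValueError(
            f"{path}: found {data.shape[1]} columns; Q, R and dR are required "
            "(simulate datasets with the synthetic module if no uncertainties "
            "are available)"
        )
    contrast = meta.get("contrast")
    if isinstance(contrast, str):
        contrast = normalize_contrast(contrast)
    return ReflectivityDataset(
        q=data[:, 0],
        r=data[:, 1],
        dr=data[:, 2],
        dq=data[:, 3] if data.shape[1] > 3 else None,
        contrast=contrast,
        instrument=meta.get("instrument"),
        meta=meta,
    )


def write_reflectivity(
    dataset: ReflectivityDataset, path, format: str | None = None
) -> Path:
    """Write a dataset as ``.ort`` (YAML-commented header) or bare ASCII."""
    path = Path(path)
    fmt = format or ("ort" if path.suffix.lower() == ".ort" else "ascii")
    cols = [dataset.q, dataset.r, dataset.dr]
    names = ["Qz (1/angstrom)", "R", "sR"]
    if dataset.dq is not None:
        cols.append(dataset.dq)
        names.append("sQz (1/angstrom, FWHM)")
    with open(path, "w") as fh:
        if fmt == "ort":
            header = {
                "orso_like": True,
                "creator": f"refmem {__version__}",
                "contrast": dataset.contrast,
                "instrument": dataset.instrument,
                "columns": names,
            }
            header.update(
                {k: v for k, v in dataset.meta.items() if k not in header}
            )
            for line in yaml.safe_dump(header, sort_keys=False).splitlines():
                fh.write(f"# {line}\n")
        else:
            fh.write("# " + "\t".join(names) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.10e")
    return path


def read_sequence(path) -> str:
    """One-letter protein sequence from a FASTA file (first record)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def packaged_sequence() -> str:
    """The shipped synthetic stand-in sequence for the truncated human enzyme.

    A constructed 366-residue surrogate (see the FASTA header): its residue
    composition reproduces the published molecular volume and solvent-contrast
    SLD series of the N-terminally truncated human enzyme, but it is not the
    natural sequence.
    """
    from importlib import resources

    text = resources.files("refmem.data").joinpath(
        "hs_dhodh_d29_synthetic.fasta"
    ).read_text()
    return "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )


# ---------------------------------------------------------------------------
# fit reports


def _layer_rows(model, result):
    """Per-layer result rows mirroring the standard table layout."""
    values = result.values
    rows = []
    cnames = list(model.contrasts)
    for lay, slug, phi_name in zip(model._layers, model._slugs, model._phi_param):
        rho0 = values[f"rho_{slug}"]
        rhos = [rho0 + off for off in model._rho_offsets[slug]]
        errs = result.stderr
        rows.append(
            {
                "layer": lay.name,
                "tau_A": values[f"tau_{slug}"],
                "tau_err": errs.get(f"tau_{slug}"),
                **{f"rho_{c}": r for c, r in zip(cnames, rhos)},
                "rho_err": errs.get(f"rho_{slug}"),
                "phi": values[phi_name],
                "phi_err": errs.get(phi_name),
                "sigma_A": values[f"sigma_{slug}"],
            }
        )
    return rows


def write_results(result, model, outdir, derived=None) -> dict[str, Path]:
    """Write a fit report: CSV layer table, JSON parameters, text summary.

    The JSON file embeds the full parameter set in lmfit's serialization so a
    reload reproduces the identical parameters.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = _layer_rows(model, result)
    df = pd.DataFrame(rows)
    paths["csv"] = outdir / "layers.csv"
    df.to_csv(paths["csv"], index=False, float_format="%.4g")

    blob = {
        "package": f"refmem {__version__}",
        "chisqr": result.chisqr,
        "redchi": result.redchi,
        "ndata": result.ndata,
        "nvarys": result.nvarys,
        "per_dataset_chisqr": result.per_dataset_chisqr,
        "seed": result.seed,
        "success": result.success,
        "parameters": json.loads(result.params.dumps()),
    }
    if derived is not None:
        blob["derived"] = {
            "coverage_volpc": derived.coverage,
            "total_thickness_A": derived.total_thickness,
            "compositions_volpc": derived.compositions,
            "area_per_lipid_A2": derived.area_per_lipid,
            "adsorbed_per_um2": derived.adsorbed,
            "protein_lipid_ratio": derived.protein_lipid_ratio,
        }
    paths["json"] = outdir / "results.json"
    paths["json"].write_text(json.dumps(blob, indent=2))

    lines = [
        f"global chi2 = {result.chisqr:.2f}  (chi2/dof = {result.redchi:.3f}, "
        f"n = {result.ndata}, free = {result.nvarys})",
        "per-contrast chi2: "
        + ", ".join(f"{k}: {v:.1f}" for k, v in result.per_dataset_chisqr.items()),
        "",
        df.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
    ]
    if derived is not None:
        lines += [
            "",
            f"coverage           {derived.coverage:.0f} vol%",
            f"total thickness    {derived.total_thickness:.0f} A",
        ]
        for name, v in derived.compositions.items():
            lines.append(f"total {name:14s} {v:.1f} vol%")
    paths["txt"] = outdir / "report.txt"
    paths["txt"].write_text("\n".join(lines) + "\n")
    return paths


def read_results(path):
    """Reload a results JSON; returns (metadata dict, lmfit.Parameters)."""
    import lmfit

    blob = json.loads(Path(path).read_text())
    params = lmfit.Parameters()
    params.loads(json.dumps(blob["parameters"]))
    return blob, params


def setup_run_log(outdir, seed: int, config_text: str = "") -> Path:
    """Write the reproducibility log: package version, seed, config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    path = outdir / "run.log"
    with open(path, "a") as fh:
        fh.write(
            f"refmem {__version__} | seed={seed} | config_sha256={digest}\n"
        )
    return path
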
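"""Reading and writing matrices, fits, and simulation truths.

Dense matrices travel as TSV/CSV (NA tokens or empty cells mark missing
entries); sparse matrices as MatrixMarket coordinate files, where absent
entries are either missing or literal zeros depending on a flag. A fitted
model is written as two TSV tables (loadings and factors, one column per
factor) plus a JSON sidecar with the priors, precision summary, objective
trace, and per-factor variance explained.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from ebmf.core import ObservedMatrix
from ebmf.ebnm import PriorSpec
from ebmf.fitting import EBMFFit, RunConfig, normalize_fit
from ebmf.simulate import SimTruth

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_fit",
    "read_fit_sidecar",
    "write_sim_truth",
    "read_sim_truth",
    "read_config",
]


def read_matrix(
    path: str | Path,
    format: str | None = None,
    na_token: str = "NA",
    mtx_zeros_missing: bool = True,
) -> ObservedMatrix:
    """Read a dense (TSV/CSV) or sparse (MTX) matrix with missing cells.

    The format is inferred from the file suffix when not given. For dense
    files, cells equal to ``na_token`` (or empty) become unobserved. For
    MatrixMarket coordinate files, entries absent from the file are
    missing when ``mtx_zeros_missing`` is true and literal zeros otherwise.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer matrix format from {path.name!r}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(
                path, sep=sep, header=None, na_values=[na_token], keep_default_na=False
            )
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        mask = ~np.isnan(values)
        return ObservedMatrix(np.where(mask, values, 0.0), mask)
    if format == "mtx":
        sp = coo_matrix(mmread(path))
        values = np.zeros(sp.shape)
        mask = np.zeros(sp.shape, dtype=bool)
        values[sp.row, sp.col] = sp.data
        if mtx_zeros_missing:
            mask[sp.row, sp.col] = True
        else:
            mask[:] = True
        return ObservedMatrix(values, mask)
    raise ValueError(f"unknown matrix format: {format!r}")


def write_matrix(
    Y: ObservedMatrix, path: str | Path, format: str = "tsv", na_token: str = "NA"
) -> None:
    """Write a matrix; unobserved cells become the NA token (dense) or are
    dropped (MTX)."""
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        cells = np.where(Y.mask, Y.values.astype(object), na_token)
        pd.DataFrame(cells).to_csv(path, sep=sep, header=False, index=False)
    elif format == "mtx":
        rows, cols = np.nonzero(Y.mask)
        sp = coo_matrix((Y.values[rows, cols], (rows, cols)), shape=Y.shape)
        mmwrite(str(path), sp)
    else:
        raise ValueError(f"unknown matrix format: {format!r}")


def _prior_to_dict(g: PriorSpec) -> dict:
    d = {"family": g.family}
    if g.pi0 is not None:
        d["pi0"] = float(g.pi0)
    if g.a is not None:
        d["a"] = float(g.a)
    if g.grid is not None:
        d["grid"] = np.asarray(g.grid).tolist()
        d["weights"] = np.asarray(g.weights).tolist()
    return d


def write_fit(fit: EBMFFit, outdir: str | Path, normalize: bool = True) -> None:
    """Write loadings.tsv, factors.tsv, and fit.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = normalize_fit(fit) if normalize else fit
    n, p = out.shape
    L = np.column_stack([fm.l_mean for fm in out.factors]) if out.K else np.zeros((n, 0))
    F = np.column_stack([fm.f_mean for fm in out.factors]) if out.K else np.zeros((p, 0))
    cols = [f"factor_{k + 1}" for k in range(out.K)]
    pd.DataFrame(L, columns=cols).to_csv(outdir / "loadings.tsv", sep="\t", index=False)
    pd.DataFrame(F, columns=cols).to_csv(outdir / "factors.tsv", sep="\t", index=False)
    obs = out.tau.tau > 0
    sidecar = {
        "K": out.K,
        "pve": np.asarray(out.pve).tolist(),
        "priors_l": [_prior_to_dict(g) for g in out.priors_l],
        "priors_f": [_prior_to_dict(g) for g in out.priors_f],
        "tau_structure": out.tau.structure,
        "tau_mean": float(out.tau.tau[obs].mean()) if obs.any() else 0.0,
        "objective_trace": [float(v) for v in out.objective_trace],
    }
    (outdir / "fit.json").write_text(json.dumps(sidecar, indent=2))


def read_fit_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_sim_truth(truth: SimTruth, outdir: str | Path) -> None:
    """Write the simulated matrix (y.tsv) and a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(truth.Y, outdir / "y.tsv", format="tsv")
    sidecar = {
        "L_true": truth.L_true.tolist(),
        "F_true": truth.F_true.tolist(),
        "tau_true": float(np.mean(truth.tau_true)),
        "seed": int(truth.seed),
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar))


def read_sim_truth(outdir: str | Path) -> SimTruth:
    outdir = Path(outdir)
    meta = json.loads((outdir / "truth.json").read_text())
    Y = read_matrix(outdir / "y.tsv", format="tsv")
    return SimTruth(
        Y=Y,
        L_true=np.asarray(meta["L_true"], dtype=float),
        F_true=np.asarray(meta["F_true"], dtype=float),
        tau_true=float(meta["tau_true"]),
        seed=int(meta["seed"]),
    )


_CONFIG_FIELDS = {
    "prior_family_l": str,
    "prior_family_f": str,
    "kmax": int,
    "tau_structure": str,
    "tol": float,
    "max_iter": int,
    "seed": int,
    "nullcheck": lambda v: v.lower() in ("1", "true", "yes"),
    "backfit": lambda v: v.lower() in ("1", "true", "yes"),
    "max_backfit_sweeps": int,
    "tau_clamp": float,
}


def read_config(path: str | Path) -> RunConfig:
    """Parse a key=value configuration file into a RunConfig.

    Lines starting with '#' and blank lines are ignored; unknown keys are
    an error. Example::

        prior_family_l = point_normal
        kmax = 10
        backfit = true
    """
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        kwargs[key] = _CONFIG_FIELDS[key](value)
    return RunConfig(**kwargs)
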
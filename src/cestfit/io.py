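"""TSV profile tables, fit-result serialization and config loading.

Profile tables are UTF-8 TSV files with fixed headers; offsets are stored
in ppm (field-independent) and converted to Hz internally using the
nucleus/field rules of :mod:`cestfit.constants`.

CEST columns:  site_id nucleus b0_T b1_Hz t_ex_s offset_ppm intensity_ratio sigma
CPMG columns:  site_id nucleus b0_T t_relax_s nu_cpmg_Hz r2_eff_s sigma
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .models import ModelSpec, Topology
from .spin_dynamics import CESTExperiment, CPMGExperiment, CESTProfile, CPMGProfile

__all__ = [
    "CEST_COLUMNS",
    "CPMG_COLUMNS",
    "ProfileParseError",
    "read_profiles",
    "write_profiles",
    "fit_result_to_dict",
    "save_fit_result",
    "load_fit_result",
]

CEST_COLUMNS = [
    "site_id",
    "nucleus",
    "b0_T",
    "b1_Hz",
    "t_ex_s",
    "offset_ppm",
    "intensity_ratio",
    "sigma",
]
CPMG_COLUMNS = [
    "site_id",
    "nucleus",
    "b0_T",
    "t_relax_s",
    "nu_cpmg_Hz",
    "r2_eff_s",
    "sigma",
]


class ProfileParseError(ValueError):
    """Malformed profile table (includes file and line information)."""


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols == CEST_COLUMNS:
        kind = "cest"
    elif cols == CPMG_COLUMNS:
        kind = "cpmg"
    else:
        raise ProfileParseError(
            f"{path}: header {cols} matches neither the CEST nor the CPMG dialect"
        )
    numeric = [c for c in cols if c not in ("site_id", "nucleus")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ProfileParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = converted
    neg = df["sigma"] <= 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ProfileParseError(f"{path}: non-positive sigma at line {line}")
    df.attrs["kind"] = kind
    return df


def read_profiles(path: Union[str, Path]):
    """Read profile TSVs from a file or a directory of ``*.tsv`` files.

    Returns a :class:`~cestfit.fitting.Dataset` holding all CEST and CPMG
    profiles found.
    """
    from .fitting import Dataset

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tsv"))
        if not files:
            raise ProfileParseError(f"no .tsv files in {path}")
    elif path.exists():
        files = [path]
    else:
        raise FileNotFoundError(path)

    data = Dataset(nuclei={})
    for f in files:
        df = _read_table(f)
        if df.attrs["kind"] == "cest":
            group_cols = ["site_id", "nucleus", "b0_T", "b1_Hz", "t_ex_s"]
            for (site, nucleus, b0, b1, t_ex), g in df.groupby(group_cols, sort=False):
                g = g.sort_values("offset_ppm")
                _register(data, site, nucleus, f)
                exp = CESTExperiment.from_ppm(
                    b0=b0,
                    b1=b1,
                    t_ex=t_ex,
                    offsets_ppm=g["offset_ppm"].to_numpy(),
                    nucleus=nucleus,
                )
                data.cest.append(
                    CESTProfile(
                        experiment=exp,
                        site_id=site,
                        intensity_ratio=g["intensity_ratio"].to_numpy(),
                        sigma=g["sigma"].to_numpy(),
                    )
                )
        else:
            group_cols = ["site_id", "nucleus", "b0_T", "t_relax_s"]
            for (site, nucleus, b0, t_relax), g in df.groupby(group_cols, sort=False):
                g = g.sort_values("nu_cpmg_Hz")
                _register(data, site, nucleus, f)
                exp = CPMGExperiment(
                    b0=b0, t_relax=t_relax, nu_cpmg=g["nu_cpmg_Hz"].to_numpy()
                )
                data.cpmg.append(
                    CPMGProfile(
                        experiment=exp,
                        site_id=site,
                        r2_eff=g["r2_eff_s"].to_numpy(),
                        sigma=g["sigma"].to_numpy(),
                    )
                )
    return data


def _register(data, site: str, nucleus: str, path: Path) -> None:
    prev = data.nuclei.get(site)
    if prev is not None and prev != nucleus:
        raise ProfileParseError(
            f"{path}: site {site!r} registered with conflicting nuclei "
            f"({prev} vs {nucleus})"
        )
    data.nuclei[site] = nucleus


def write_profiles(data, directory: Union[str, Path]) -> List[Path]:
    """Write a Dataset to ``cest.tsv`` / ``cpmg.tsv`` inside ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if data.cest:
        rows = []
        for p in data.cest:
            nucleus = data.nuclei[p.site_id]
            ppm = p.experiment.offsets_ppm(nucleus)
            sigma = (
                p.sigma if p.sigma is not None else np.full(len(ppm), np.nan)
            )
            for o, y, s in zip(ppm, p.intensity_ratio, sigma):
                rows.append(
                    (
                        p.site_id,
                        nucleus,
                        p.experiment.b0,
                        p.experiment.b1,
                        p.experiment.t_ex,
                        o,
                        y,
                        s,
                    )
                )
        df = pd.DataFrame(rows, columns=CEST_COLUMNS)
        out = directory / "cest.tsv"
        df.to_csv(out, sep="\t", index=False, float_format="%.10g")
        written.append(out)
    if data.cpmg:
        rows = []
        for p in data.cpmg:
            nucleus = data.nuclei[p.site_id]
            sigma = (
                p.sigma if p.sigma is not None else np.full(len(p.r2_eff), np.nan)
            )
            for nu, r, s in zip(p.experiment.nu_cpmg, p.r2_eff, sigma):
                rows.append(
                    (
                        p.site_id,
                        nucleus,
                        p.experiment.b0,
                        p.experiment.t_relax,
                        nu,
                        r,
                        s,
                    )
                )
        df = pd.DataFrame(rows, columns=CPMG_COLUMNS)
        out = directory / "cpmg.tsv"
        df.to_csv(out, sep="\t", index=False, float_format="%.10g")
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# fit-result serialization


def fit_result_to_dict(fit) -> Dict:
    spec = fit.spec
    return {
        "spec": {
            "topology": spec.topology.value,
            "states": list(spec.states),
            "r2_mode": spec.r2_mode,
            "r1_mode": spec.r1_mode,
            "r1_value": spec.r1_value,
            "sign_constraints": dict(spec.sign_constraints),
        },
        "best_values": {k: float(v) for k, v in fit.best_values.items()},
        "chi2_red": float(fit.chi2_red),
        "n_data": int(fit.n_data),
        "n_params": int(fit.n_params),
        "per_site_shifts": fit.per_site_shifts,
        "per_site_r2": fit.per_site_r2,
        "per_site_r1": fit.per_site_r1,
        "uncertainties": {k: float(v) for k, v in fit.uncertainties.items()},
        "convergence": {k: v for k, v in fit.convergence.items()},
    }


def save_fit_result(fit, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=1, default=float))


def load_fit_result(path: Union[str, Path]):
    """Load a serialized fit result (spec + values sufficient to rebuild
    the exchange model and the free-energy observables)."""
    from .fitting import FitResult

    d = json.loads(Path(path).read_text())
    s = d["spec"]
    spec = ModelSpec(
        topology=Topology(s["topology"]),
        states=tuple(s["states"]),
        r2_mode=s["r2_mode"],
        r1_mode=s["r1_mode"],
        r1_value=s["r1_value"],
        sign_constraints={k: int(v) for k, v in s["sign_constraints"].items()},
    )
    return FitResult(
        spec=spec,
        best_values=d["best_values"],
        chi2_red=d["chi2_red"],
        n_data=d["n_data"],
        n_params=d["n_params"],
        per_site_shifts=d["per_site_shifts"],
        per_site_r2=d["per_site_r2"],
        per_site_r1=d["per_site_r1"],
        uncertainties=d["uncertainties"],
        convergence=d["convergence"],
    )
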
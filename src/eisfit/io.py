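"""CSV dialects, key-value config files and run manifests.

All files are plain text.  Spectrum CSVs use the header
``frequency_hz,z_real_ohm,z_imag_ohm`` (Cartesian) or
``frequency_hz,z_mod_ohm,z_phase_rad`` (polar, auto-detected); metadata
travels in leading ``# key = value`` comment lines.  Titration and
voltammogram files follow the same convention.  Config files are flat
``section.key = value`` text.  Every stochastic command writes a JSON run
manifest recording inputs, config and seed so results can be regenerated
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationSeries, Voltammogram
from .circuit import PARAM_NAMES, CircuitParameters, ImpedanceSpectrum, polar_to_cartesian
from .cohort import RctCohort
from .likelihood import FitResult, ParameterBounds
from .mcmc import PosteriorSamples

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_titration",
    "write_titration",
    "read_voltammogram",
    "write_voltammogram",
    "read_cohorts",
    "write_fit",
    "read_fit",
    "write_posterior",
    "read_posterior",
    "read_config",
    "bounds_from_config",
    "write_manifest",
]

CARTESIAN_HEADER = ["frequency_hz", "z_real_ohm", "z_imag_ohm"]
POLAR_HEADER = ["frequency_hz", "z_mod_ohm", "z_phase_rad"]
_SPECTRUM_META_KEYS = ("e_dc_v", "e_ac_v", "t_equil_s")


class FormatError(ValueError):
    """Raised when a file does not match a known dialect."""


def _read_comment_metadata(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value.strip())
                except ValueError:
                    meta[key.strip()] = value.strip()  # type: ignore[assignment]
    return meta


def _read_table(path: Path, expected_headers: list[list[str]]) -> tuple[pd.DataFrame, list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    columns = [c.strip() for c in frame.columns]
    for header in expected_headers:
        if columns == header:
            bad = frame.columns[frame.apply(lambda s: pd.to_numeric(s, errors="coerce")).isna().any()]
            if len(bad):
                rows = frame[frame.apply(lambda s: pd.to_numeric(s, errors="coerce")).isna().any(axis=1)]
                raise FormatError(
                    f"{path}: non-numeric value(s) in column(s) {list(bad)} "
                    f"(first bad data row: {int(rows.index[0]) + 2})"
                )
            return frame.astype(float), header
    expected = " or ".join(",".join(h) for h in expected_headers)
    raise FormatError(f"{path}: unknown header {','.join(columns)!r}; expected {expected}")


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum CSV, auto-detecting the Cartesian or polar dialect."""
    path = Path(path)
    frame, header = _read_table(path, [CARTESIAN_HEADER, POLAR_HEADER])
    meta = {k: v for k, v in _read_comment_metadata(path).items() if k in _SPECTRUM_META_KEYS}
    freq = frame["frequency_hz"].to_numpy()
    if header == CARTESIAN_HEADER:
        z_real = frame["z_real_ohm"].to_numpy()
        z_imag = frame["z_imag_ohm"].to_numpy()
    else:
        z_real, z_imag = polar_to_cartesian(
            frame["z_mod_ohm"].to_numpy(), frame["z_phase_rad"].to_numpy()
        )
    return ImpedanceSpectrum(freq, z_real, z_imag, metadata=meta)


def write_spectrum(spectrum: ImpedanceSpectrum, path, polar: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key in _SPECTRUM_META_KEYS:
            if key in spectrum.metadata:
                fh.write(f"# {key} = {spectrum.metadata[key]}\n")
        if polar:
            fh.write(",".join(POLAR_HEADER) + "\n")
            for f, m, p in zip(spectrum.frequencies, spectrum.magnitude, spectrum.phase):
                fh.write(f"{float(f)!r},{float(m)!r},{float(p)!r}\n")
        else:
            fh.write(",".join(CARTESIAN_HEADER) + "\n")
            for f, zr, zi in zip(spectrum.frequencies, spectrum.z_real, spectrum.z_imag):
                fh.write(f"{float(f)!r},{float(zr)!r},{float(zi)!r}\n")


def read_titration(path) -> TitrationSeries:
    path = Path(path)
    frame, _ = _read_table(path, [["concentration_ug_ml", "rct_ohm"]])
    meta = _read_comment_metadata(path)
    if "rct0_ohm" not in meta:
        raise FormatError(f"{path}: missing '# rct0_ohm = <value>' metadata line")
    return TitrationSeries(
        rct_0=float(meta["rct0_ohm"]),
        concentrations=frame["concentration_ug_ml"].to_numpy(),
        rct=frame["rct_ohm"].to_numpy(),
    )


def write_titration(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rct0_ohm = {float(series.rct_0)!r}\n")
        fh.write("concentration_ug_ml,rct_ohm\n")
        for c, r in zip(series.concentrations, series.rct):
            fh.write(f"{float(c)!r},{float(r)!r}\n")


def read_voltammogram(path) -> Voltammogram:
    path = Path(path)
    frame, _ = _read_table(path, [["potential_v", "current_a"]])
    meta = _read_comment_metadata(path)
    if "scan_rate_v_s" not in meta:
        raise FormatError(f"{path}: missing '# scan_rate_v_s = <value>' metadata line")
    return Voltammogram(
        potential=frame["potential_v"].to_numpy(),
        current=frame["current_a"].to_numpy(),
        scan_rate=float(meta["scan_rate_v_s"]),
    )


def write_voltammogram(vgram: Voltammogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scan_rate_v_s = {float(vgram.scan_rate)!r}\n")
        fh.write("potential_v,current_a\n")
        for e, i in zip(vgram.potential, vgram.current):
            fh.write(f"{float(e)!r},{float(i)!r}\n")


def read_cohorts(path) -> dict[str, RctCohort]:
    """Read a cohort CSV ``label,rct_ohm[,age_days]`` into per-label cohorts."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    columns = [c.strip() for c in frame.columns]
    if columns not in (["label", "rct_ohm"], ["label", "rct_ohm", "age_days"]):
        raise FormatError(
            f"{path}: unknown header; expected label,rct_ohm[,age_days]"
        )
    cohorts = {}
    for label, group in frame.groupby("label", sort=False):
        ages = group["age_days"].to_numpy(float) if "age_days" in columns else None
        cohorts[str(label)] = RctCohort(
            label=str(label), values=group["rct_ohm"].to_numpy(float), ages=ages
        )
    return cohorts


def write_fit(fit: FitResult, path) -> None:
    """Flat key-value record of the seven parameters plus fit bookkeeping."""
    with open(path, "w") as fh:
        for name in PARAM_NAMES:
            fh.write(f"{name} = {float(getattr(fit.best_fit, name))!r}\n")
        fh.write(f"log_likelihood = {float(fit.log_likelihood_value)!r}\n")
        fh.write(f"n_evaluations = {fit.n_evaluations}\n")
        fh.write(f"seed = {fit.seed}\n")
        fh.write(f"converged = {fit.converged}\n")


def read_fit(path) -> FitResult:
    values = read_config(path)
    params = CircuitParameters(**{n: float(values[n]) for n in PARAM_NAMES})
    return FitResult(
        best_fit=params,
        log_likelihood_value=float(values["log_likelihood"]),
        n_evaluations=int(values["n_evaluations"]),
        seed=int(values["seed"]),
        converged=str(values["converged"]).lower() in ("true", "1"),
    )


def write_posterior(samples: PosteriorSamples, path) -> None:
    """Posterior CSV: one column per parameter plus chain and iteration."""
    n_chains, n_iter, d = samples.chains.shape
    with open(path, "w") as fh:
        fh.write(f"# burn_in = {samples.burn_in}\n")
        fh.write(f"# seed = {samples.seed}\n")
        fh.write("chain,iteration," + ",".join(samples.param_names) + "\n")
        for c in range(n_chains):
            for i in range(n_iter):
                row = ",".join(repr(float(v)) for v in samples.chains[c, i])
                fh.write(f"{c},{i},{row}\n")


def read_posterior(path) -> PosteriorSamples:
    path = Path(path)
    meta = _read_comment_metadata(path)
    frame = pd.read_csv(path, comment="#")
    n_chains = int(frame["chain"].max()) + 1
    n_iter = int(frame["iteration"].max()) + 1
    names = [c for c in frame.columns if c not in ("chain", "iteration")]
    chains = np.empty((n_chains, n_iter, len(names)))
    for c in range(n_chains):
        block = frame[frame["chain"] == c].sort_values("iteration")
        chains[c] = block[names].to_numpy(float)
    return PosteriorSamples(
        chains=chains,
        burn_in=int(meta.get("burn_in", 0)),
        seed=int(meta.get("seed", 0)),
        param_names=tuple(names),
    )


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` config text; '#' starts a comment, blanks ignored."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    return values


def bounds_from_config(path) -> ParameterBounds:
    """Read ``param.lower = value`` / ``param.upper = value`` boundary files."""
    raw = read_config(path)
    pairs: dict[str, dict[str, float]] = {}
    for key, value in raw.items():
        name, _, side = key.partition(".")
        if side not in ("lower", "upper"):
            raise FormatError(f"{path}: bound keys must end in .lower or .upper, got {key!r}")
        pairs.setdefault(name, {})[side] = float(value)
    mapping = {}
    for name, sides in pairs.items():
        if set(sides) != {"lower", "upper"}:
            raise FormatError(f"{path}: parameter {name!r} needs both .lower and .upper")
        mapping[name] = (sides["lower"], sides["upper"])
    return ParameterBounds.from_mapping(mapping)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def write_manifest(
    command: str,
    out_path,
    inputs: list | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Append a JSON run manifest next to ``out_path``.

    Records the command, input digests, config, seed, package version and
    timestamp; with the same inputs, config and seed any result file can be
    regenerated bit-identically.
    """
    from . import __version__

    out_path = Path(out_path)
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    entry = {
        "command": command,
        "inputs": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "config": config or {},
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "output": str(out_path),
    }
    existing = []
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text())
    existing.append(entry)
    manifest_path.write_text(json.dumps(existing, indent=2) + "\n")
    return manifest_path
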
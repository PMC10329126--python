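"""Reading and writing samples, scenario configs, and result artifacts.

Canonical input is single-column numeric text (one failure time per
line, ``#`` comments allowed); CSV with a named or indexed column is
supported for convenience.  Zero, negative or non-finite entries are
rejected with a line-numbered message — the model's support is strictly
positive.  Every artifact written carries enough metadata (parameters,
seed, package version) to re-derive it exactly.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import NBPVFParams, nbpvf_rvs
from .estimation import Sample
from .simulation import SimDesign

__all__ = [
    "read_sample",
    "write_sample",
    "synth",
    "load_scenario",
    "load_bundled_dataset",
    "BUNDLED_DATASETS",
]

# plain-text fixtures transcribed from the cited primary sources
BUNDLED_DATASETS = {
    "reactor_pumps": "reactor_pumps.txt",
    "electronic_machines": "electronic_machines.txt",
}


def _validate_positive(values: np.ndarray, lines=None) -> np.ndarray:
    bad = ~np.isfinite(values) | (values <= 0)
    if np.any(bad):
        idx = int(np.argmax(bad))
        where = f"line {lines[idx]}" if lines is not None else f"entry {idx + 1}"
        raise ValueError(
            f"invalid failure time {values[idx]!r} at {where}: "
            "values must be finite and strictly positive"
        )
    return values


def read_sample(path, column=None) -> Sample:
    """Read a sample from plain text (default) or CSV (``column`` given).

    Plain text: one number per line, blank lines and ``#`` comments
    skipped.  CSV: ``column`` selects a header name or 0-based index.
    """
    path = Path(path)
    if column is not None or path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if column is None:
            column = 0
        col = df.iloc[:, int(column)] if isinstance(column, int) or str(column).isdigit() else df[column]
        values = col.to_numpy(dtype=float)
        return Sample(_validate_positive(values))

    values, lines = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        if "," in text and "." in text.replace(",", ""):
            pass  # "1,234.5" style rejected below by float()
        try:
            values.append(float(text))
        except ValueError as exc:
            raise ValueError(f"unparsable value {text!r} at line {lineno}") from exc
        lines.append(lineno)
    if not values:
        raise ValueError(f"no data found in {path}")
    return Sample(_validate_positive(np.asarray(values, dtype=float), lines))


def write_sample(values, path) -> None:
    """Write one failure time per line."""
    path = Path(path)
    path.write_text("".join(f"{float(v)!r}\n" for v in np.asarray(values, dtype=float)))


def synth(params: NBPVFParams, n: int, seed: int, out_path) -> Path:
    """Draw a reproducible sample and write it plus a JSON sidecar.

    The sidecar records (params, n, seed) so the file re-derives exactly
    via ``nbpvf_rvs(n, params, seed)``.
    """
    p = NBPVFParams(*params).validate()
    out_path = Path(out_path)
    values = nbpvf_rvs(n, p, seed=seed)
    write_sample(values, out_path)
    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "params": {"alpha": p.alpha, "sigma": p.sigma, "beta": p.beta},
                "n": int(n),
                "seed": int(seed),
                "generator": "numpy.random.default_rng(seed) -> inverse CDF",
            },
            indent=2,
        )
        + "\n"
    )
    return out_path


def load_scenario(path) -> SimDesign:
    """Load a simulation scenario from a JSON key-value file.

    Keys: ``alpha``, ``sigma``, ``beta`` (truth), ``sizes`` (list),
    ``reps``, ``seed``.
    """
    cfg = json.loads(Path(path).read_text())
    return SimDesign(
        true_params=NBPVFParams(cfg["alpha"], cfg["sigma"], cfg["beta"]),
        sizes=tuple(cfg.get("sizes", range(50, 1001, 50))),
        reps=int(cfg.get("reps", 1000)),
        seed=int(cfg.get("seed", 0)),
    )


def load_bundled_dataset(name: str) -> Sample:
    """Load one of the bundled transcribed application datasets."""
    if name not in BUNDLED_DATASETS:
        raise KeyError(f"unknown dataset {name!r}; choose from {sorted(BUNDLED_DATASETS)}")
    ref = resources.files("nbpvf").joinpath("data", BUNDLED_DATASETS[name])
    values = [
        float(t)
        for line in ref.read_text().splitlines()
        if (t := line.split("#", 1)[0].strip())
    ]
    return Sample(values)
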
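"""Packaged datasets and input parsing.

The single packaged dataset is the rate of persons fully vaccinated against
COVID-19 per 100 population in 46 African countries (snapshot from the public
vaccination-coverage record), a classic heavy-tailed positive sample: most
countries below 5 per 100, a long tail out to 72 per 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distribution import ObservationSet

__all__ = ["Dataset", "COVID_VACCINATION_AFRICA", "load_dataset", "read_sample",
           "summary_stats"]

_COVID_VALUES = (
    0.042, 0.205, 0.285, 0.319, 0.464, 0.550, 0.889, 0.895, 0.939, 0.986,
    1.000, 1.088, 1.212, 1.244, 1.450, 1.593, 1.844, 2.039, 2.157, 2.167,
    2.334, 2.440, 2.657, 3.685, 3.879, 4.493, 4.800, 4.944, 5.155, 5.674,
    7.602, 10.004, 12.238, 12.520, 12.553, 13.063, 15.105, 15.229, 15.629,
    15.848, 18.641, 18.940, 29.885, 58.162, 61.838, 72.286,
)


@dataclass(frozen=True)
class Dataset:
    name: str
    values: ObservationSet
    source: str = ""


COVID_VACCINATION_AFRICA = Dataset(
    name="covid_vaccination_africa",
    values=ObservationSet(_COVID_VALUES),
    source="fully-vaccinated persons per 100, 46 African countries",
)

_FIXTURES = {COVID_VACCINATION_AFRICA.name: COVID_VACCINATION_AFRICA}


def load_dataset(name: str) -> Dataset:
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


def read_sample(source) -> ObservationSet:
    """Read a univariate positive sample.

    `source` may be a packaged dataset name, or a path to a plain-text /
    single-column CSV file with one positive real per line (an optional
    non-numeric header row is skipped).  Input order is preserved.
    """
    if isinstance(source, str) and source in _FIXTURES:
        return _FIXTURES[source].values
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such file or dataset: {source!r}")
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip().split(",")[0].strip()
            if not token:
                continue
            try:
                v = float(token)
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ValueError(f"line {lineno}: {token!r} is not a number") from None
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"line {lineno}: value {v} must be finite and > 0")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return ObservationSet(values)


def summary_stats(data: ObservationSet) -> dict:
    """Minimum, quartiles, median, mean, maximum and sample variance.

    Quartiles use linear interpolation between order statistics (R type 7,
    numpy's default); the variance uses the n-1 denominator.
    """
    x = np.asarray(data)
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return {
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "mean": float(x.mean()),
        "q3": float(q3),
        "max": float(x.max()),
        "variance": float(x.var(ddof=1)),
        "n": int(x.size),
    }
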
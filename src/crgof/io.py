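"""Plain-text data I/O.

Data files hold only the observed lifetimes — one value per line or several
per line, whitespace- or comma-separated; lines starting with ``#`` are
comments.  Censoring is metadata (the total trial count n and observed
count r), never encoded in the file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .mle import CensoredSample

__all__ = ["ParseError", "read_data", "write_data"]


class ParseError(ValueError):
    """A data file failed to parse; the message names the offending line."""


def read_data(
    path, n_override: Optional[int] = None, r_override: Optional[int] = None
) -> CensoredSample:
    """Read a censored sample from a plain-text file.

    The file holds the observed values.  ``r_override`` (must be <= the
    count in the file) keeps only the r smallest order statistics;
    ``n_override`` (>= r) declares the total number on test.  Without
    overrides the sample is treated as complete.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            for token in body.replace(",", " ").split():
                try:
                    values.append(float(token))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: cannot parse {token!r} as a number"
                    ) from None
    if not values:
        raise ParseError(f"{path}: no data values found")
    x = np.sort(np.asarray(values))
    r = len(values) if r_override is None else int(r_override)
    if r > len(values) or r < 1:
        raise ValueError(f"r={r} must lie in [1, {len(values)}] for this file")
    n = r if n_override is None else int(n_override)
    if n < r:
        raise ValueError(f"n={n} must be >= r={r}")
    return CensoredSample(x[:r], n=n)


def write_data(sample_or_values, path, header: Optional[str] = None) -> None:
    """Write values one per line, with an optional ``#`` header comment."""
    values = getattr(sample_or_values, "observed", None)
    if values is None:
        values = getattr(sample_or_values, "values", sample_or_values)
    path = Path(path)
    lines = []
    if header:
        lines += [f"# {l}" for l in header.splitlines()]
    lines += [repr(float(v)) for v in np.asarray(values, dtype=float)]
    path.write_text("\n".join(lines) + "\n")
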
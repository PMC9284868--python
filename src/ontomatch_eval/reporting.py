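"""Rounding and formatting helpers shared by reports and the CLI.

Scores are reported to two decimals, percentages to the nearest integer
(one decimal below 1%), ties rounded away from zero.  Raw floats are kept
internally everywhere; rounding happens only at the reporting boundary.
"""

from __future__ import annotations

import decimal
import hashlib
import json
import platform
from pathlib import Path


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (unlike banker's ``round``)."""
    quant = decimal.Decimal(10) ** -ndigits
    rounded = decimal.Decimal(repr(float(value))).quantize(
        quant, rounding=decimal.ROUND_HALF_UP
    )
    return float(rounded)


def format_score(value: float | None) -> str:
    """Two-decimal score, or the undefined marker 'NA'."""
    if value is None:
        return "NA"
    return f"{round_half_away(value, 2):.2f}"


def format_delta(after: float | None, before: float | None) -> str:
    """Signed two-decimal delta in the '+0.0X' style ('NA' if undefined)."""
    if after is None or before is None:
        return "NA"
    delta = round_half_away(after, 2) - round_half_away(before, 2)
    return f"{delta:+.2f}"


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, seed: int | None, inputs: dict[str, str]) -> None:
    """Record a run's provenance: package version, platform, seed and
    SHA-256 digests of every input file."""
    from . import __version__

    manifest = {
        "tool": "ontomatch-eval",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "inputs": {name: file_digest(p) for name, p in inputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
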
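"""key=value configuration file parsing.

Recognized keys (all optional; missing keys take the package defaults):

  flank_len         int, bp per breakpoint flank       (default 30)
  min_overlap       int, bp                            (default 15)
  driver_threshold  float in [0, 1]                    (default 0.7)
  exclude_prefixes  comma-separated gene-name prefixes (default built-in list)
  tissue            EPI | HEM | MES | AVG              (no default; only
                    needed when a driver-score input file is requested)
  tie_break_order   comma-separated permutation of the four structure labels

Lines starting with '#' and blank lines are ignored.  Unknown keys are an
error, so typos never silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .model import PipelineConfig, ValidationError

__all__ = ["parse_config"]

_KEYS = {
    "flank_len",
    "min_overlap",
    "driver_threshold",
    "exclude_prefixes",
    "tissue",
    "tie_break_order",
}


def parse_config(path: Union[str, Path]) -> PipelineConfig:
    """Parse a key=value configuration file into a PipelineConfig."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in _KEYS:
                raise ValidationError(f"{path}:{lineno}: unknown configuration key {key!r}")
            if key in values:
                raise ValidationError(f"{path}:{lineno}: duplicate key {key!r}")
            values[key] = value.strip()

    kwargs: dict = {}
    try:
        if "flank_len" in values:
            kwargs["flank_len"] = int(values["flank_len"])
        if "min_overlap" in values:
            kwargs["min_overlap"] = int(values["min_overlap"])
        if "driver_threshold" in values:
            kwargs["driver_threshold"] = float(values["driver_threshold"])
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    if "exclude_prefixes" in values:
        kwargs["exclude_prefixes"] = tuple(
            p.strip() for p in values["exclude_prefixes"].split(",") if p.strip()
        )
    if "tissue" in values:
        kwargs["tissue"] = values["tissue"]
    if "tie_break_order" in values:
        kwargs["tie_break_order"] = tuple(
            p.strip() for p in values["tie_break_order"].split(",") if p.strip()
        )
    return PipelineConfig(**kwargs)
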
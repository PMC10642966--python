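"""Run configuration: TOML-backed, echoed into every output directory."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .control import ControlParams
from .io import DEFAULT_GRID, UNFOLDED_EXTENT_MM
from .registration import RegParams


@dataclass
class RunConfig:
    grid_shape: tuple[int, int] = DEFAULT_GRID
    unfolded_extent_mm: tuple[float, float] = UNFOLDED_EXTENT_MM
    solver_tol: float = 1e-5
    solver_max_iter: int = 10_000
    morphometry_sigma_mm: float = 1.0
    seed: int = 42
    reg: RegParams = field(default_factory=RegParams)
    control: ControlParams = field(default_factory=ControlParams)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "reg":
                v = RegParams(**{k: tuple(x) if isinstance(x, list) else x
                                 for k, x in v.items()})
            elif f.name == "control":
                sub = dict(v)
                if "reg" in sub:
                    sub["reg"] = RegParams(
                        **{k: tuple(x) if isinstance(x, list) else x
                           for k, x in sub["reg"].items()})
                v = ControlParams(**sub)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_toml(self, path) -> None:
        Path(path).write_text(_emit_toml(dataclasses.asdict(self)))


def _emit_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_emit_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def _emit_toml(d: dict, prefix: str = "") -> str:
    lines = []
    tables = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {_emit_value(v)}")
    out = "\n".join(lines)
    for k, v in tables:
        name = f"{prefix}{k}"
        out += f"\n\n[{name}]\n" + _emit_toml(v, prefix=name + ".")
    return out.strip() + "\n"
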
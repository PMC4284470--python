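"""Run configuration, file outputs and hand-written chemistry import.

All artifacts are plain text: chemistries as JSON, trajectories and
generation records as CSV (with the config hash and seed in a header
comment line), diagnostics as JSON, graphs as DOT/GraphML.  A tab-separated
reaction-list import is provided for small hand-written chemistries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chemistry import Chemistry, KineticParams, Reaction, Species
from .container import ContainerGeometry

__all__ = [
    "RunConfig",
    "config_hash",
    "write_records_csv",
    "write_trajectory_csv",
    "write_json",
    "write_graphml",
    "read_reactions_tsv",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: (config, seed) -> outputs."""

    chemistry: str | None = None       # path to a chemistry JSON
    fixture: str | None = None         # or a named fixture
    fixture_params: dict = field(default_factory=dict)
    mode: str = "instantaneous"
    delta: float = 2.0
    rho: float = 10.0
    theta: float = 20000.0
    C0: float | None = None            # default theta/2
    g: int = 1
    seed: int = 0
    n_generations: int = 25
    horizon_per_generation: float = 1e4
    max_events_per_generation: int = 10_000_000
    partition_mode: str = "trinomial_with_loss"
    follow: str = "first"
    injections: list = field(default_factory=list)  # [gen, species, copies]

    def geometry(self) -> ContainerGeometry:
        return ContainerGeometry(
            delta=self.delta,
            rho=self.rho,
            theta=self.theta,
            C=self.theta / 2.0 if self.C0 is None else self.C0,
            g=self.g,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(cfg) -> str:
    """Short stable hash of a config mapping (or RunConfig)."""
    if isinstance(cfg, RunConfig):
        cfg = cfg.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg_hash: str, seed) -> str:
    return f"# config_hash={cfg_hash} seed={seed}\n"


def write_records_csv(result, path, cfg_hash="", seed="") -> Path:
    """Generation records (division-time counts, dT) as CSV."""
    path = Path(path)
    df = result.division_counts()
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash, seed))
        df.to_csv(fh, index=False)
    return path


def write_trajectory_csv(traj, path, cfg_hash="", seed="") -> Path:
    path = Path(path)
    df = traj.to_frame()
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash, seed))
        df.to_csv(fh, index=False)
    return path


def write_json(obj, path, cfg_hash="", seed="") -> Path:
    path = Path(path)
    payload = {"config_hash": cfg_hash, "seed": seed, "data": obj}
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_graphml(graph, path) -> Path:
    import networkx as nx

    path = Path(path)
    nx.write_graphml(graph, path)
    return path


def read_reactions_tsv(path, chem: Chemistry) -> list[Reaction]:
    """Import hand-written reactions into ``chem``.

    Tab-separated columns: kind, substrates (joined by '+'), products
    (joined by '+'), catalysts (comma-separated, may be empty).  Lines
    starting with '#' are skipped.  Referenced species are created.
    """
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed reaction line: {raw!r}")
        kind = parts[0].strip()
        subs = tuple(s.strip() for s in parts[1].split("+"))
        prods = tuple(s.strip() for s in parts[2].split("+"))
        cats = frozenset(
            c.strip() for c in (parts[3].split(",") if len(parts) > 3 else [])
            if c.strip()
        )
        cut = len(prods[0]) if kind == "cleavage" else None
        r = Reaction(kind=kind, substrates=subs, products=prods,
                     cut_position=cut, catalysts=cats)
        for seq in (*subs, *prods, *cats):
            chem.ensure_species(seq)
        chem.reactions.append(r)
        out.append(r)
    return out
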
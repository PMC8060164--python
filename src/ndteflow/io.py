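"""Delimited-text readers/writers, run configuration, and the pipeline driver.

Panels are tab-delimited rectangles (rows = regions, columns = timepoints)
with an optional leading label column; matrices carry a label header row and
column.  Every written artifact gets a JSON sidecar or manifest recording
the parameters and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clubs import FricDetector, intersect_gw
from .hierarchy import flow_profiles
from .inference import GroupNDTE
from .ndte import FlowMatrix
from .signals import EmbeddingSpec, TimeSeriesPanel


class PanelParseError(ValueError):
    """Malformed delimited panel or matrix file."""


def read_panel(path: str | Path, tr: float, subject_id: str | None = None,
               condition: str = "rest") -> TimeSeriesPanel:
    """Read a delimited panel (rows = regions); optional first label column."""
    path = Path(path)
    rows: list[list[float]] = []
    labels: list[str] = []
    has_labels: bool | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.replace(",", "\t").split("\t")
            cells = [c for c in cells if c != ""]
            if has_labels is None:
                try:
                    float(cells[0])
                    has_labels = False
                except ValueError:
                    has_labels = True
            if has_labels:
                labels.append(cells[0])
                cells = cells[1:]
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                bad = next(c for c in cells if not _is_number(c))
                raise PanelParseError(
                    f"{path}:{lineno}: non-numeric cell {bad!r} in column "
                    f"{cells.index(bad) + 1}"
                ) from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise PanelParseError(
                    f"{path}:{lineno}: row has {len(rows[-1])} cells, expected {len(rows[0])}"
                )
    if not rows:
        raise PanelParseError(f"{path}: empty panel")
    return TimeSeriesPanel(
        data=np.array(rows),
        tr=tr,
        subject_id=subject_id or path.stem,
        condition=condition,
        region_labels=labels,
    )


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    """Write a panel with a leading label column (tab-delimited)."""
    path = Path(path)
    with path.open("w") as fh:
        for label, row in zip(panel.region_labels, panel.data):
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square delimited matrix with an optional label header row/column."""
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise PanelParseError(f"{path}: empty matrix")
    first = lines[0].replace(",", "\t").split("\t")
    has_header = not _is_number(first[-1])
    labels: list[str] = []
    values: list[list[float]] = []
    body = lines[1:] if has_header else lines
    for ln in body:
        cells = [c for c in ln.replace(",", "\t").split("\t") if c != ""]
        if has_header:
            labels.append(cells[0])
            cells = cells[1:]
        values.append([float(c) for c in cells])
    mat = np.array(values)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise PanelParseError(f"{path}: matrix is not square (shape {mat.shape})")
    if not labels:
        labels = [f"R{i:03d}" for i in range(mat.shape[0])]
    return mat, labels


def write_matrix(values: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write a labeled square matrix (tab-delimited, header row and column)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, np.asarray(values)):
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def write_flow_matrix(flow: FlowMatrix, path: str | Path) -> None:
    """Flow matrix as delimited text plus a JSON sidecar with provenance."""
    path = Path(path)
    write_matrix(flow.values, flow.region_labels, path)
    sidecar = {
        "T": flow.embedding.T,
        "units": "normalized flow (unit interval)",
        "orientation": "rows=targets, columns=sources",
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_flow_matrix(path: str | Path) -> FlowMatrix:
    values, labels = read_matrix(path)
    sidecar_path = Path(str(path) + ".json")
    T = 10
    if sidecar_path.exists():
        T = int(json.loads(sidecar_path.read_text()).get("T", 10))
    return FlowMatrix(values=values, region_labels=labels, embedding=EmbeddingSpec(T=T))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one panel directory per condition)."""

    panels: dict[str, list[str]]  # condition -> panel file paths
    out_dir: str
    tr: float = 0.72
    T: int = 10
    n_surrogates: int = 100
    q: float = 0.05
    fric_alpha: float = 0.05
    seed: int = 0
    min_count: int | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for cond, paths in cfg.panels.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"panel file {p} (condition {cond}) does not exist")
        return cfg


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Group flow -> hierarchy -> club detection per condition -> GW intersection.

    Writes every intermediate artifact under ``config.out_dir`` and returns
    the manifest (also written as ``manifest.json``).  Reruns with existing
    outputs are skipped unless ``force``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    if manifest_path.exists() and not force:
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == config_hash:
            return manifest
    manifest: dict = {
        "version": __version__,
        "config_hash": config_hash,
        "seed": config.seed,
        "conditions": {},
        "stages": [],
    }
    frics = []
    for cond, paths in sorted(config.panels.items()):
        t0 = time.time()
        panels = [read_panel(p, tr=config.tr, condition=cond) for p in paths]
        est = GroupNDTE(
            T=config.T, n_surrogates=config.n_surrogates, q=config.q, seed=config.seed
        ).fit(panels)
        flow = est.flow_matrix_
        flow_path = out / f"flow_{cond}.tsv"
        write_flow_matrix(flow, flow_path)
        sig = est.significance_
        for name, mat in (
            ("stouffer", sig.stouffer),
            ("group_p", sig.group_pvalues),
            ("mask", sig.mask),
        ):
            write_matrix(mat, flow.region_labels, out / f"{name}_{cond}.tsv")
        prof = flow_profiles(flow)
        with (out / f"hierarchy_{cond}.tsv").open("w") as fh:
            fh.write("region\tg_in\tg_out\tg_tot\n")
            for lbl, gi, go, gt in zip(prof.region_labels, prof.g_in, prof.g_out, prof.g_tot):
                fh.write(f"{lbl}\t{gi:.12g}\t{go:.12g}\t{gt:.12g}\n")
        det = FricDetector(alpha=config.fric_alpha, seed=config.seed).fit(flow)
        fric = det.result_
        frics.append(fric)
        (out / f"fric_{cond}.json").write_text(
            json.dumps(
                {
                    "members": fric.members,
                    "member_labels": [flow.region_labels[i] for i in fric.members],
                    "scores": fric.scores,
                    "step_pvalues": fric.step_pvalues,
                    "alpha": fric.alpha,
                    "no_club": fric.no_club,
                },
                indent=2,
            )
        )
        manifest["conditions"][cond] = {
            "n_subjects": len(panels),
            "flow": flow_path.name,
            "fric_members": fric.members,
            "wall_time_s": round(time.time() - t0, 3),
        }
        manifest["stages"].append({"stage": f"group+fric:{cond}", "ok": True})
    gw = intersect_gw(frics, min_count=config.min_count)
    labels = frics[0].region_labels if frics else []
    (out / "gw.json").write_text(
        json.dumps({"members": gw, "member_labels": [labels[i] for i in gw]}, indent=2)
    )
    manifest["gw"] = gw
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
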
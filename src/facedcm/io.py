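"""Plain-text serialization: TSV tables with JSON sidecars.

Designs, region time series and evidence matrices travel as tab-separated
text; model structures and posteriors as JSON.  A time-series TSV has one
column per region and a ``<name>.json`` sidecar with the repetition time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bms import EvidenceMatrix
from .forward import BOLDDataset, DCMSpec
from .paradigm import Block, BlockDesign

__all__ = [
    "write_design", "read_design",
    "write_series", "read_series",
    "write_model_space", "read_model_space",
    "write_evidence", "read_evidence",
    "write_posterior",
]


def write_design(design: BlockDesign, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [(b.onset_s, b.duration_s, b.condition, b.run) for b in design.blocks],
        columns=["onset_s", "duration_s", "condition", "run"],
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "tr_s": design.tr_s, "n_scans": design.n_scans,
        "run_boundaries": design.run_boundaries, "seed": design.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_design(path: str | Path) -> BlockDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    blocks = [Block(r.onset_s, r.duration_s, r.condition, int(r.run))
              for r in df.itertuples()]
    return BlockDesign(blocks, list(meta["run_boundaries"]), meta["tr_s"],
                       int(meta["n_scans"]), seed=meta.get("seed"))


def write_series(data: BOLDDataset, path: str | Path, units: str = "a.u.") -> None:
    path = Path(path)
    pd.DataFrame(data.series, columns=list(data.region_names)).to_csv(
        path, sep="\t", index=False)
    sidecar = {"tr_s": data.tr_s, "units": units,
               "subject_id": data.subject_id, "group": data.group}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_series(path: str | Path) -> BOLDDataset:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return BOLDDataset(
        series=df.to_numpy(float), tr_s=meta["tr_s"],
        subject_id=meta.get("subject_id", ""), group=meta.get("group"),
        region_names=tuple(df.columns),
    )


def _spec_to_dict(spec: DCMSpec) -> dict:
    return {
        "regions": list(spec.regions),
        "input_labels": list(spec.input_labels),
        "a_mask": spec.a_mask.tolist(),
        "b_masks": spec.b_masks.tolist(),
        "c_mask": spec.c_mask.tolist(),
        "family_id": spec.family_id,
        "combo": list(spec.combo) if spec.combo else None,
    }


def write_model_space(specs: list[DCMSpec], path: str | Path) -> None:
    """One JSON object per line (audit-friendly)."""
    with open(path, "w") as fh:
        for spec in specs:
            fh.write(json.dumps(_spec_to_dict(spec)) + "\n")


def read_model_space(path: str | Path) -> list[DCMSpec]:
    specs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        specs.append(DCMSpec(
            a_mask=np.array(d["a_mask"]), b_masks=np.array(d["b_masks"]),
            c_mask=np.array(d["c_mask"]), regions=tuple(d["regions"]),
            input_labels=tuple(d["input_labels"]), family_id=d["family_id"],
            combo=tuple(d["combo"]) if d["combo"] else None,
        ))
    return specs


def write_evidence(em: EvidenceMatrix, path: str | Path) -> None:
    path = Path(path)
    cols = [f"model_{i}" for i in range(em.n_models)]
    df = pd.DataFrame(em.F, columns=cols)
    df.insert(0, "subject", em.subjects or [f"sub-{i:02d}" for i in range(em.n_subjects)])
    if em.groups:
        df.insert(1, "group", em.groups)
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(json.dumps(
        {"model_tags": [list(map(str, t)) if isinstance(t, (list, tuple)) else str(t)
                        for t in em.model_tags]}, indent=1))


def read_evidence(path: str | Path) -> EvidenceMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    subjects = df.pop("subject").tolist() if "subject" in df else []
    groups = df.pop("group").tolist() if "group" in df else []
    tags: list = []
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        tags = json.loads(sidecar.read_text()).get("model_tags", [])
    return EvidenceMatrix(df.to_numpy(float), model_tags=tags,
                          subjects=subjects, groups=groups)


def write_posterior(results, path: str | Path) -> None:
    """Posterior moments and settings of one inversion as JSON."""
    cov = results.cov_params()
    tril = cov[np.tril_indices_from(cov)]
    out = {
        "param_names": results.param_names,
        "mean": results.params.tolist(),
        "cov_lower_triangle": tril.tolist(),
        "free_energy": results.free_energy,
        "converged": results.converged,
        "n_iter": results.n_iter,
        "noise_precision": np.asarray(results.noise_precision).tolist(),
        "prior_mean": results.model.priors.mu.tolist(),
        "prior_var": results.model.priors.var.tolist(),
    }
    Path(path).write_text(json.dumps(out, indent=1))
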
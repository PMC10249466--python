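"""Reading and writing study tables and manifests.

A study on disk is one TSV per variable group (first column = sample id,
header = variable names) plus a YAML manifest listing, per group: ``file``,
``name``, ``role`` and optional flags (``compositional``, ``units``,
``dose_response``).
"""

from __future__ import annotations

import os

import pandas as pd
import yaml

from .data_model import VariableGroup
from .exceptions import ValidationError

MANIFEST_NAME = "manifest.yaml"


def read_group_table(path, name: str, role: str, meta: dict | None = None) -> VariableGroup:
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    return VariableGroup(name=name, role=role, data=frame, meta=dict(meta or {}))


def write_group_table(group: VariableGroup, path) -> None:
    header_bits = []
    if "alr_reference" in group.meta:
        header_bits.append(
            f"# alr_reference={group.meta['alr_reference']} pseudocount={group.meta['pseudocount']}"
        )
    with open(path, "w") as fh:
        for line in header_bits:
            fh.write(line + "\n")
        group.data.to_csv(fh, sep="\t", index_label="sample")


def read_manifest(path) -> list[VariableGroup]:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "groups" not in manifest:
        raise ValidationError(f"manifest {path!r} must contain a top-level 'groups' list")
    base = os.path.dirname(os.path.abspath(path))
    groups = []
    for entry in manifest["groups"]:
        meta = {
            k: v
            for k, v in entry.items()
            if k not in ("file", "name", "role")
        }
        fpath = entry["file"]
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        groups.append(read_group_table(fpath, entry["name"], entry["role"], meta))
    return groups


def write_study_tables(groups: list[VariableGroup], outdir) -> str:
    """Write one TSV per group plus a manifest; returns the manifest path."""
    os.makedirs(outdir, exist_ok=True)
    entries = []
    for g in groups:
        fname = f"{g.name}.tsv"
        write_group_table(g, os.path.join(outdir, fname))
        entry = {"file": fname, "name": g.name, "role": g.role}
        for key in ("compositional", "units", "dose_response", "layer"):
            if key in g.meta:
                entry[key] = g.meta[key]
        entries.append(entry)
    manifest_path = os.path.join(outdir, MANIFEST_NAME)
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"groups": entries}, fh, sort_keys=False)
    return manifest_path
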
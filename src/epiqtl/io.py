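"""TSV file formats and run configuration.

Three flat tab-separated inputs describe a family:

* map file — ``group<TAB>marker<TAB>position_cM``, sorted by group then
  position;
* genotype file — ``id`` plus one column per marker, cells are the
  two-character codes ``13``/``14``/``23``/``24`` (P1 allele then P2
  allele);
* phenotype file — ``id<TAB>value``, one trait per file.

Results are written as a flat table mirroring the in-memory report: one
row per QTL pair with positions, LR, threshold, the 16 effect estimates,
the residual variance and the 15 effect-test LRs.  All writes go through
a temp-file-plus-rename so partially written files never appear.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .genetic_model import EFFECT_NAMES, LOCUS_GENOTYPES
from .structures import FamilyDataset, LinkageGroup, LinkageMap

__all__ = [
    "RunConfig",
    "load_config",
    "read_linkage_map",
    "read_dataset",
    "write_dataset",
    "result_columns",
    "write_result_table",
    "atomic_write_text",
]

#: fixed column layout of the result table (38 columns)
result_columns: tuple[str, ...] = (
    ("group1", "pos1_cM", "group2", "pos2_cM", "LR", "LR_threshold")
    + EFFECT_NAMES
    + ("sigma2",)
    + tuple(f"lr_{name}" for name in EFFECT_NAMES[1:])
)


@dataclass
class RunConfig:
    """Flat key/value configuration with documented defaults."""

    step_cM: float = 2.0
    n_perm: int = 1000
    alpha: float = 0.05
    em_tol: float = 1e-8
    em_max_iter: int = 2000
    seed: Optional[int] = None
    min_class_mass: float = 1e-10


def load_config(path: str) -> RunConfig:
    """Read a flat ``key: value`` config file; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be flat key/value pairs")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def atomic_write_text(path: str, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_linkage_map(path: str) -> LinkageMap:
    """Parse a map file into a :class:`LinkageMap`."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "marker": str})
    expected = ["group", "marker", "position_cM"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header must be {expected}, got {list(df.columns)}")
    groups = []
    seen_groups: list[str] = []
    for name, sub in df.groupby("group", sort=False):
        if name in seen_groups:
            raise ValueError(f"{path}: group {name!r} appears in non-contiguous blocks")
        seen_groups.append(str(name))
        pos = sub["position_cM"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(pos) <= 0)
        if bad.size:
            line = sub.index[bad[0] + 1] + 2  # +1 row, +1 header (1-based)
            raise ValueError(
                f"{path}: line {line}: positions not strictly increasing in "
                f"group {name!r}"
            )
        groups.append(
            LinkageGroup(name=str(name), markers=tuple(sub["marker"]), positions=pos)
        )
    return LinkageMap(groups=tuple(groups))


def _parse_genotypes(
    geno_path: str, linkage_map: LinkageMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(geno_path, sep="\t", dtype=str)
    if df.columns[0] != "id":
        raise ValueError(f"{geno_path}: first column must be 'id'")
    markers = tuple(df.columns[1:])
    if markers != linkage_map.marker_names:
        raise ValueError(
            f"{geno_path}: marker columns do not match the map "
            f"(expected {linkage_map.marker_names})"
        )
    codes = df.iloc[:, 1:].to_numpy(dtype="U2")
    valid = {f"{a}{b}" for a in "12" for b in "34"}
    bad = ~np.isin(codes, sorted(valid))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{geno_path}: line {i + 2}, column {markers[j]!r}: invalid "
            f"genotype code {codes[i, j]!r} (expected one of "
            f"{sorted(valid)})"
        )
    numeric = codes.astype(np.int16)
    p1 = (numeric // 10).astype(np.int8)
    p2 = (numeric % 10).astype(np.int8)
    return df["id"].to_numpy(), p1, p2


def read_dataset(map_path: str, geno_path: str, pheno_path: str) -> FamilyDataset:
    """Load and cross-validate the three input files.

    Offspring follow the phenotype-file order; genotype rows are aligned
    to it by id.
    """
    lm = read_linkage_map(map_path)
    geno_ids, p1, p2 = _parse_genotypes(geno_path, lm)
    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"id": str})
    if list(pheno.columns) != ["id", "value"]:
        raise ValueError(f"{pheno_path}: header must be ['id', 'value']")
    values = pheno["value"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        line = int(np.flatnonzero(~np.isfinite(values))[0]) + 2
        raise ValueError(f"{pheno_path}: line {line}: non-finite phenotype")
    index = {str(g): k for k, g in enumerate(geno_ids)}
    if len(index) != len(geno_ids):
        raise ValueError(f"{geno_path}: duplicate offspring ids")
    order = []
    for row, ind in enumerate(pheno["id"]):
        if str(ind) not in index:
            raise ValueError(
                f"{pheno_path}: line {row + 2}: id {ind!r} missing from the "
                "genotype file"
            )
        order.append(index[str(ind)])
    order = np.asarray(order, dtype=int)
    return FamilyDataset(
        linkage_map=lm,
        ids=pheno["id"].to_numpy(dtype=str),
        p1_alleles=p1[order],
        p2_alleles=p2[order],
        phenotypes=values,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_dataset(
    dataset: FamilyDataset,
    map_path: str,
    geno_path: str,
    pheno_path: str,
    truth_path: Optional[str] = None,
) -> None:
    """Write a dataset back to the three TSV files (plus optional truth)."""
    lm = dataset.linkage_map
    lines = ["group\tmarker\tposition_cM"]
    for g in lm.groups:
        for m, p in zip(g.markers, g.positions):
            lines.append(f"{g.name}\t{m}\t{_fmt(p)}")
    atomic_write_text(map_path, "\n".join(lines) + "\n")

    header = "id\t" + "\t".join(lm.marker_names)
    rows = [header]
    for i, ind in enumerate(dataset.ids):
        cells = [
            f"{dataset.p1_alleles[i, j]}{dataset.p2_alleles[i, j]}"
            for j in range(lm.n_markers)
        ]
        rows.append(str(ind) + "\t" + "\t".join(cells))
    atomic_write_text(geno_path, "\n".join(rows) + "\n")

    rows = ["id\tvalue"] + [
        f"{ind}\t{_fmt(v)}" for ind, v in zip(dataset.ids, dataset.phenotypes)
    ]
    atomic_write_text(pheno_path, "\n".join(rows) + "\n")

    if truth_path is not None:
        if dataset.truth is None:
            raise ValueError("dataset carries no simulation truth to write")
        t = dataset.truth
        from .genetic_model import TWO_LOCUS_GENOTYPES

        rows = [
            f"# qtl1\t{t['qtl1']}",
            f"# qtl2\t{t['qtl2']}",
            f"# sigma2\t{_fmt(t['sigma2'])}",
            f"# heritability\t{_fmt(t['heritability'])}",
            "id\ttrue_genotype",
        ]
        for ind, g in zip(dataset.ids, t["genotype_index"]):
            rows.append(f"{ind}\t{TWO_LOCUS_GENOTYPES[g]}")
        atomic_write_text(truth_path, "\n".join(rows) + "\n")


def write_result_table(rows: list[dict], path: str) -> None:
    """Write result rows (dicts keyed by :data:`result_columns`) as TSV.

    Missing numeric fields serialise as ``NA``; floats carry 6 significant
    digits.
    """
    out = ["\t".join(result_columns)]
    for row in rows:
        cells = []
        for col in result_columns:
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                cells.append("NA")
            elif isinstance(v, float):
                cells.append(_fmt(v))
            else:
                cells.append(str(v))
        out.append("\t".join(cells))
    atomic_write_text(path, "\n".join(out) + "\n")
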
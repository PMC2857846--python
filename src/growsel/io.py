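"""Plain-text file formats and run manifests.

Everything is TSV/CSV (diffable, adequate at this data scale — thousands of
individuals by hundreds of SNPs).  Exact column contracts live in
``docs/formats.md``; every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import LongitudinalDataset, SimConfig, SimTruth

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_snp_map",
    "write_snp_map",
    "write_dataset",
    "read_dataset",
    "write_manifest",
    "config_hash",
]

_VALID_CODES = {1, 2, 3}


class FormatError(ValueError):
    """A file does not follow its documented format."""


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    """Genotype table: TSV, ``individual_id`` then one column per SNP (codes 1/2/3)."""
    genotypes.to_csv(path, sep="\t", index=True, index_label="individual_id")


def read_genotypes(path) -> pd.DataFrame:
    """Read and validate a genotype table (codes 1/2/3, unique individuals)."""
    tab = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in tab.columns:
        raise FormatError(f"{path}: missing 'individual_id' column")
    dup = tab["individual_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicated individual id {tab['individual_id'][dup].iloc[0]!r}"
        )
    tab = tab.set_index("individual_id")
    vals = tab.to_numpy()
    bad = ~np.isin(vals, list(_VALID_CODES))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype code {vals[r, c]!r} for individual "
            f"{tab.index[r]!r}, column {tab.columns[c]!r} (expected 1, 2 or 3)"
        )
    return tab.astype(np.int64)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    """Phenotype records: CSV with columns individual_id, time, yield."""
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read long-format phenotype records; time order preserved per individual."""
    tab = pd.read_csv(path, dtype={"individual_id": str})
    required = ["individual_id", "time", "yield"]
    if list(tab.columns[:3]) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(tab.columns)}")
    for col in ("time", "yield"):
        vals = pd.to_numeric(tab[col], errors="coerce")
        if tab[col].notna().any() and vals.isna().any():
            bad = tab.loc[vals.isna(), col].iloc[0]
            raise FormatError(f"{path}: non-numeric {col} value {bad!r}")
        tab[col] = vals
    dup = tab.duplicated(subset=["individual_id", "time"])
    if dup.any():
        row = tab[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate record for individual {row['individual_id']!r} "
            f"at time {row['time']!r}"
        )
    return tab.sort_values(["individual_id", "time"], kind="stable").reset_index(drop=True)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    """Pedigree: CSV with individual_id, sire, dam, family, set."""
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    tab = pd.read_csv(path, dtype={"individual_id": str, "sire": str, "dam": str})
    required = {"individual_id", "sire", "dam", "family", "set"}
    missing = required - set(tab.columns)
    if missing:
        raise FormatError(f"{path}: missing pedigree columns {sorted(missing)}")
    bad = ~tab["set"].isin(["training", "candidate"])
    if bad.any():
        raise FormatError(f"{path}: invalid set value {tab.loc[bad, 'set'].iloc[0]!r}")
    return tab


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    """SNP map: TSV with snp_id, chrom, pos_morgan."""
    snp_map.to_csv(path, sep="\t", index=False)


def read_snp_map(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos_morgan"}
    missing = required - set(tab.columns)
    if missing:
        raise FormatError(f"{path}: missing SNP-map columns {sorted(missing)}")
    return tab


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping (for log lines/manifests)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path, *, config: dict, seed: int | None, stage: str) -> None:
    """Run manifest: config, seed and versions — enough to reproduce the run."""
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def write_dataset(dataset: LongitudinalDataset, outdir) -> None:
    """Write a simulated dataset: genotypes, phenotypes, pedigree, map, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(dataset.genotypes, outdir / "genotypes.tsv")
    write_phenotypes(dataset.phenotypes, outdir / "phenotypes.csv")
    write_pedigree(dataset.pedigree, outdir / "pedigree.csv")
    write_snp_map(dataset.snp_map, outdir / "snp_map.tsv")
    if dataset.truth is not None:
        dataset.truth.qtl_table.to_csv(outdir / "truth_qtl.csv", index=False)
        dataset.truth.tbv.to_csv(outdir / "truth_tbv.csv")
    cfg = asdict(dataset.config) if dataset.config is not None else {}
    write_manifest(
        outdir / "manifest.yaml", config=cfg, seed=dataset.seed, stage="simulate"
    )


def read_dataset(indir, with_truth: bool = True) -> LongitudinalDataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    genotypes = read_genotypes(indir / "genotypes.tsv")
    phenotypes = read_phenotypes(indir / "phenotypes.csv")
    pedigree = read_pedigree(indir / "pedigree.csv")
    snp_map = read_snp_map(indir / "snp_map.tsv")
    truth = None
    tbv_path = indir / "truth_tbv.csv"
    if with_truth and tbv_path.exists():
        tbv = pd.read_csv(tbv_path, dtype={"individual_id": str}).set_index("individual_id")
        qtl = pd.read_csv(indir / "truth_qtl.csv")
        manifest_path = indir / "manifest.yaml"
        cfg = SimConfig()
        if manifest_path.exists():
            with open(manifest_path) as fh:
                manifest = yaml.safe_load(fh)
            known = {f.name for f in SimConfig.__dataclass_fields__.values()}
            raw = {
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in (manifest.get("config") or {}).items()
                if k in known
            }
            cfg = SimConfig(**raw)
        truth = SimTruth(qtl_table=qtl, tbv=tbv, mean_params=cfg.mean_params)
    return LongitudinalDataset(
        genotypes=genotypes,
        phenotypes=phenotypes,
        pedigree=pedigree,
        snp_map=snp_map,
        truth=truth,
    )
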
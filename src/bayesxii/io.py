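"""File formats: genotype matrices, phenotypes, chain traces, augmentations.

Text formats are documented in docs/FORMATS.md.  Genotypes are accepted
either as a plain whitespace-delimited 0/1/2 matrix or in the PLINK ``.raw``
additive dialect (six leading columns FID IID PAT MAT SEX PHENOTYPE, then
one column per marker).  Chain traces are split into a delimited scalar
file and an HDF5 container for the thinned marker-effect samples;
augmentations are stored in HDF5 with a provenance hash of the source
genotypes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .conventional import ChainTrace
from .oda import Augmentation
from .sim_data import GenotypeData, TraitData

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "write_qtl_table",
    "write_trace",
    "read_trace",
    "save_augmentation",
    "load_augmentation",
]

TRACE_VERSION = 1
_PLINK_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _validate_codes(M: pd.DataFrame, path: str) -> np.ndarray:
    arr = M.to_numpy()
    num = pd.to_numeric(pd.Series(arr.ravel()), errors="coerce").to_numpy()
    bad = ~np.isin(num, (0.0, 1.0, 2.0)) | ~np.isfinite(num)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        r, c = divmod(flat, arr.shape[1])
        raise ValueError(
            f"{path}: invalid genotype code {arr[r, c]!r} at row {r + 1}, "
            f"marker column {c + 1} (expected 0/1/2)"
        )
    return num.reshape(arr.shape).astype(np.float64)


def read_genotype_matrix(path: str | Path, dialect: str = "raw-matrix") -> GenotypeData:
    """Parse a 0/1/2 genotype file.

    ``dialect='raw-matrix'``: whitespace-delimited numeric matrix, one row
    per individual, no header.  ``dialect='plink-raw'``: PLINK .raw export
    with header; the six leading columns are skipped and marker names are
    retained from the header.  Missing (NA) or out-of-alphabet codes raise
    with the offending coordinates.
    """
    path = Path(path)
    if dialect == "raw-matrix":
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        if df.isna().any().any():
            raise ValueError(f"{path}: ragged or missing entries")
        X = _validate_codes(df, str(path))
        ids = np.array([f"id{i:06d}" for i in range(X.shape[0])])
        names = None
    elif dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing = [c for c in _PLINK_LEAD if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: not a PLINK .raw file; missing {missing}")
        names = [c for c in df.columns if c not in _PLINK_LEAD]
        ids = df["IID"].to_numpy()
        X = _validate_codes(df[names], str(path))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    freq = X.mean(axis=0) / 2.0
    return GenotypeData(ids=ids, X=X, allele_freq=freq, centered=False,
                        kept_loci=np.arange(X.shape[1]), marker_names=names)


def write_genotype_matrix(G: GenotypeData, path: str | Path,
                          dialect: str = "raw-matrix") -> None:
    """Write 0/1/2 genotypes in either text dialect (uncentered only)."""
    if G.centered:
        raise ValueError("refusing to write a centered matrix as 0/1/2 codes")
    path = Path(path)
    Xr = np.rint(G.X)
    if np.max(np.abs(np.asarray(G.X, float) - Xr)) > 1e-6:
        raise ValueError("genotype matrix entries are not integer codes")
    Xi = Xr.astype(np.int64)
    if dialect == "raw-matrix":
        np.savetxt(path, Xi, fmt="%d", delimiter=" ")
    elif dialect == "plink-raw":
        names = G.marker_names or [f"snp{j + 1}_A" for j in range(G.p)]
        with open(path, "w") as fh:
            fh.write(" ".join(_PLINK_LEAD + list(names)) + "\n")
            for i in range(G.n):
                lead = [str(G.ids[i]), str(G.ids[i]), "0", "0", "0", "-9"]
                fh.write(" ".join(lead + [str(v) for v in Xi[i]]) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_phenotypes(T: TraitData, ids: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"id": ids, "y": T.y, "bv": T.bv}).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: phenotype file needs 'id' and 'y' columns")
    return df


def write_qtl_table(T: TraitData, path: str | Path) -> None:
    pd.DataFrame({"locus": T.qtl_idx, "effect": T.qtl_effects}).to_csv(
        path, index=False)


def write_trace(trace: ChainTrace, prefix: str | Path) -> tuple[Path, Path]:
    """Write a trace as <prefix>.scalars.csv + <prefix>.effects.h5."""
    prefix = Path(prefix)
    scalars = prefix.with_suffix(".scalars.csv")
    effects = prefix.with_suffix(".effects.h5")
    pd.DataFrame({
        "iteration": np.arange(1, trace.length + 1),
        "mu": trace.mu,
        "pi": trace.pi,
        "sigma2_a": trace.sigma2_a,
        "sigma2_e": trace.sigma2_e,
        "n_included": trace.n_included,
    }).to_csv(scalars, index=False)
    with h5py.File(effects, "w") as h5:
        h5.attrs["version"] = TRACE_VERSION
        h5.attrs["length"] = trace.length
        h5.attrs["thin"] = trace.thin
        h5.attrs["seed"] = trace.seed
        h5.attrs["chain_index"] = trace.chain_index
        h5.attrs["variant"] = trace.variant
        h5.create_dataset("a_samples", data=trace.a_samples)
        h5.create_dataset("a_mean", data=trace.a_mean)
        h5.create_dataset("initial_a", data=trace.initial.get(
            "a", np.empty(0)))
    return scalars, effects


def read_trace(prefix: str | Path) -> ChainTrace:
    """Round-trip counterpart of write_trace; errors on version mismatch."""
    prefix = Path(prefix)
    scalars = prefix.with_suffix(".scalars.csv")
    effects = prefix.with_suffix(".effects.h5")
    df = pd.read_csv(scalars)
    try:
        h5 = h5py.File(effects, "r")
    except OSError as exc:
        raise ValueError(f"{effects}: unreadable or truncated trace file") from exc
    with h5:
        if int(h5.attrs.get("version", -1)) != TRACE_VERSION:
            raise ValueError(
                f"{effects}: trace version {h5.attrs.get('version')} != "
                f"{TRACE_VERSION}")
        length = int(h5.attrs["length"])
        if len(df) != length:
            raise ValueError(f"{scalars}: truncated scalar trace "
                             f"({len(df)} rows, expected {length})")
        trace = ChainTrace(
            length=length,
            thin=int(h5.attrs["thin"]),
            seed=int(h5.attrs["seed"]),
            chain_index=int(h5.attrs["chain_index"]),
            variant=str(h5.attrs["variant"]),
            mu=df["mu"].to_numpy(),
            pi=df["pi"].to_numpy(),
            sigma2_a=df["sigma2_a"].to_numpy(),
            sigma2_e=df["sigma2_e"].to_numpy(),
            n_included=df["n_included"].to_numpy(),
            a_samples=h5["a_samples"][()],
            a_mean=h5["a_mean"][()],
            initial={"a": h5["initial_a"][()]},
        )
    return trace


def save_augmentation(aug: Augmentation, path: str | Path,
                      source_hash: str | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["version"] = TRACE_VERSION
        h5.attrs["d"] = aug.d
        h5.attrs["jitter"] = aug.jitter
        if source_hash or aug.source_hash:
            h5.attrs["source_hash"] = source_hash or aug.source_hash
        h5.create_dataset("J_tilde", data=aug.J_tilde)
        h5.create_dataset("X_tilde", data=aug.X_tilde)


def load_augmentation(path: str | Path) -> Augmentation:
    with h5py.File(path, "r") as h5:
        return Augmentation(
            d=float(h5.attrs["d"]),
            jitter=float(h5.attrs["jitter"]),
            J_tilde=h5["J_tilde"][()],
            X_tilde=h5["X_tilde"][()],
            source_hash=(str(h5.attrs["source_hash"])
                         if "source_hash" in h5.attrs else None),
        )
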
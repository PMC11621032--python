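"""Readers/writers for layered count matrices, gene sets, and QC filters.

Supported on-disk formats for paired spliced/unspliced matrices:

* **loom** — HDF5 with the loom layout (``/matrix`` genes x cells,
  ``/layers/{spliced,unspliced}``, ``row_attrs/Gene``, ``col_attrs/CellID``,
  optional ``col_attrs/batch``), written/read directly through h5py;
* **anndata** — ``.h5ad`` with ``layers["spliced"]`` / ``layers["unspliced"]``
  and an optional ``obs["batch"]`` column;
* **mtx_pair** — MatrixMarket ``<prefix>_spliced.mtx`` /
  ``<prefix>_unspliced.mtx`` with ``<prefix>_genes.tsv`` and
  ``<prefix>_cells.tsv`` name files (cells file may carry a second
  ``batch`` column).

Gene filtering follows the fitting pipeline order: gene-set intersection,
then mean-count thresholds (genes with mean unspliced <= 0.1 or mean
spliced <= 0.3 per cell are dropped by default), then fit-based filters on
the unspliced-spliced expectation-curve correlation and peak delay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix, issparse

from .containers import CountDataset
from .core import fourier_basis

__all__ = [
    "GeneSet",
    "FilterReport",
    "load_gene_set",
    "read_dataset",
    "write_dataset",
    "filter_genes",
    "filter_by_fit",
    "save_manifold_fit",
    "load_manifold_fit",
    "save_velocity_fit",
]

_BUNDLED_SIZES = {"small": 97, "medium": 218, "large": 1918}


@dataclass
class GeneSet:
    """A named list of cycling genes.

    The bundled ``small``/``medium``/``large`` sets are *synthetic
    stand-ins* with the conventional sizes (97/218/1,918): the curated
    literature lists are third-party resources that are not redistributed
    here.  For real analyses supply a custom list (one symbol per line).
    """

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set is empty")
        if len(set(g.upper() for g in self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicate identifiers")

    def __len__(self) -> int:
        return len(self.genes)


def normalize_symbol_case(genes: list[str], species: str = "human") -> list[str]:
    """Species casing helper: human symbols upper-case, mouse title-case."""
    if species == "human":
        return [g.upper() for g in genes]
    if species == "mouse":
        return [g.capitalize() for g in genes]
    raise ValueError(f"unknown species {species!r}")


def load_gene_set(name_or_path: str, species: str | None = None) -> GeneSet:
    """Load a bundled (``small``/``medium``/``large``) or custom gene set."""
    if name_or_path in _BUNDLED_SIZES:
        ref = resources.files("circvelo").joinpath(f"data/gene_set_{name_or_path}_synthetic.txt")
        lines = ref.read_text().splitlines()
        name = name_or_path
    else:
        lines = Path(name_or_path).read_text().splitlines()
        name = "custom"
    genes = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if species is not None:
        genes = normalize_symbol_case(genes, species)
    return GeneSet(name=name, genes=genes)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def _as_int_matrix(x, round_values: bool) -> np.ndarray:
    x = np.asarray(x.todense()) if issparse(x) else np.asarray(x)
    if not np.allclose(x, np.round(x)):
        if not round_values:
            raise ValueError(
                "matrix contains non-integer values; pass round_values=True to round"
            )
        x = np.round(x)
    return x.astype(np.int64)


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    spliced_layer: str = "spliced",
    unspliced_layer: str = "unspliced",
    round_values: bool = False,
) -> CountDataset:
    """Read a paired spliced/unspliced dataset; format inferred from suffix."""
    path = Path(path)
    if fmt is None:
        if path.suffix == ".loom":
            fmt = "loom"
        elif path.suffix in (".h5ad", ".h5"):
            fmt = "anndata"
        else:
            fmt = "mtx_pair"
    if fmt == "loom":
        with h5py.File(path, "r") as f:
            layers = f["layers"]
            for name in (spliced_layer, unspliced_layer):
                if name not in layers:
                    raise KeyError(
                        f"layer {name!r} not found; available: {sorted(layers.keys())}"
                    )
            S = _as_int_matrix(layers[spliced_layer][:].T, round_values)
            U = _as_int_matrix(layers[unspliced_layer][:].T, round_values)
            genes = [g.decode() if isinstance(g, bytes) else str(g)
                     for g in f["row_attrs/Gene"][:]]
            cells = [c.decode() if isinstance(c, bytes) else str(c)
                     for c in f["col_attrs/CellID"][:]]
            batch = None
            if "batch" in f["col_attrs"]:
                batch = np.array(
                    [b.decode() if isinstance(b, bytes) else b for b in f["col_attrs/batch"][:]]
                )
        return CountDataset(S=S, U=U, cell_ids=cells, gene_ids=genes, batch=batch)
    if fmt == "anndata":
        import anndata as ad

        adata = ad.read_h5ad(path)
        for name in (spliced_layer, unspliced_layer):
            if name not in adata.layers:
                raise KeyError(
                    f"layer {name!r} not found; available: {sorted(adata.layers.keys())}"
                )
        S = _as_int_matrix(adata.layers[spliced_layer], round_values)
        U = _as_int_matrix(adata.layers[unspliced_layer], round_values)
        batch = adata.obs["batch"].to_numpy() if "batch" in adata.obs else None
        return CountDataset(
            S=S, U=U, cell_ids=list(adata.obs_names), gene_ids=list(adata.var_names),
            batch=batch,
        )
    if fmt == "mtx_pair":
        prefix = str(path)
        S = _as_int_matrix(mmread(f"{prefix}_spliced.mtx"), round_values)
        U = _as_int_matrix(mmread(f"{prefix}_unspliced.mtx"), round_values)
        genes = pd.read_csv(f"{prefix}_genes.tsv", sep="\t", header=None)
        cells = pd.read_csv(f"{prefix}_cells.tsv", sep="\t", header=None)
        if S.shape[1] != len(genes):
            raise ValueError(
                f"gene file lists {len(genes)} genes but matrix has {S.shape[1]} columns"
            )
        if S.shape != U.shape:
            raise ValueError("spliced and unspliced matrices have different shapes")
        batch = cells[1].to_numpy() if cells.shape[1] > 1 else None
        return CountDataset(
            S=S, U=U, cell_ids=list(cells[0]), gene_ids=list(genes[0]), batch=batch
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(data: CountDataset, path: str | Path, fmt: str | None = None) -> None:
    """Write a dataset as loom, h5ad, or an MTX pair (prefix path)."""
    path = Path(path)
    if fmt is None:
        fmt = "loom" if path.suffix == ".loom" else (
            "anndata" if path.suffix == ".h5ad" else "mtx_pair"
        )
    if fmt == "loom":
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=data.S.T)
            layers = f.create_group("layers")
            layers.create_dataset("spliced", data=data.S.T)
            layers.create_dataset("unspliced", data=data.U.T)
            ra = f.create_group("row_attrs")
            ra.create_dataset("Gene", data=np.array(data.gene_ids, dtype="S"))
            ca = f.create_group("col_attrs")
            ca.create_dataset("CellID", data=np.array(data.cell_ids, dtype="S"))
            if data.batch is not None:
                ca.create_dataset("batch", data=np.array(data.batch, dtype="S"))
        return
    if fmt == "anndata":
        import anndata as ad

        adata = ad.AnnData(
            X=csr_matrix(data.S),
            layers={"spliced": csr_matrix(data.S), "unspliced": csr_matrix(data.U)},
        )
        adata.obs_names = data.cell_ids
        adata.var_names = data.gene_ids
        if data.batch is not None:
            adata.obs["batch"] = data.batch
        adata.write_h5ad(path)
        return
    if fmt == "mtx_pair":
        prefix = str(path)
        mmwrite(f"{prefix}_spliced.mtx", csr_matrix(data.S))
        mmwrite(f"{prefix}_unspliced.mtx", csr_matrix(data.U))
        pd.Series(data.gene_ids).to_csv(f"{prefix}_genes.tsv", sep="\t", header=False, index=False)
        cells = pd.DataFrame({0: data.cell_ids})
        if data.batch is not None:
            cells[1] = data.batch
        cells.to_csv(f"{prefix}_cells.tsv", sep="\t", header=False, index=False)
        return
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Bookkeeping of the gene-filtering funnel (counts never increase)."""

    n_input_genes: int
    n_after_set_intersection: int
    n_after_mean_filters: int
    n_after_correlation_delay_filters: int | None = None
    thresholds: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def filter_genes(
    data: CountDataset,
    gene_set: GeneSet | None = None,
    min_mean_u: float = 0.1,
    min_mean_s: float = 0.3,
) -> tuple[CountDataset, FilterReport]:
    """Keep gene-set members with mean U > ``min_mean_u`` and mean S > ``min_mean_s``.

    Thresholds are strict: a gene whose mean sits exactly at the boundary
    is removed.
    """
    if min_mean_u < 0 or min_mean_s < 0:
        raise ValueError("thresholds must be nonnegative")
    n_input = data.n_genes
    if gene_set is not None:
        wanted = {g.upper() for g in gene_set.genes}
        mask_set = np.array([g.upper() in wanted for g in data.gene_ids])
    else:
        mask_set = np.ones(n_input, dtype=bool)
    n_set = int(mask_set.sum())
    mean_u = data.U.mean(axis=0)
    mean_s = data.S.mean(axis=0)
    mask = mask_set & (mean_u > min_mean_u) & (mean_s > min_mean_s)
    n_mean = int(mask.sum())
    if n_mean == 0:
        raise ValueError(
            "no genes survive filtering; lower min_mean_u/min_mean_s or widen the gene set"
        )
    report = FilterReport(
        n_input_genes=n_input,
        n_after_set_intersection=n_set,
        n_after_mean_filters=n_mean,
        thresholds={"min_mean_u": min_mean_u, "min_mean_s": min_mean_s},
    )
    return data.subset_genes(mask), report


def filter_by_fit(
    data: CountDataset,
    manifold_s,
    manifold_u,
    min_us_corr: float = 0.8,
    min_delay: float = -0.25,
    min_amplitude: float = 1e-3,
    n_grid: int = 100,
    use_raw_counts: bool = False,
) -> tuple[CountDataset, FilterReport]:
    """Keep genes whose unspliced and spliced behavior is velocity-informative.

    Retained genes must have (i) Pearson correlation >= ``min_us_corr``
    between the fitted unspliced and spliced expectation curves evaluated
    on a phase grid (or between raw U and S counts when
    ``use_raw_counts``), and (ii) an unspliced-spliced peak delay
    >= ``min_delay`` radians.  Genes with near-zero harmonic amplitude have
    no defined peak and are removed first.
    """
    from .posterior import delays as _delays

    table = _delays(manifold_s, manifold_u, min_amplitude=min_amplitude)
    if use_raw_counts:
        Sc = data.S - data.S.mean(axis=0)
        Uc = data.U - data.U.mean(axis=0)
        denom = np.sqrt((Sc**2).sum(axis=0) * (Uc**2).sum(axis=0))
        corr = np.where(denom > 0, (Sc * Uc).sum(axis=0) / denom, 0.0)
    else:
        grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
        k = manifold_s.n_harmonics
        zeta = fourier_basis(grid, k)
        es = zeta @ manifold_s.nu_loc.T
        eu = zeta @ manifold_u.nu_loc.T
        esc = es - es.mean(axis=0)
        euc = eu - eu.mean(axis=0)
        denom = np.sqrt((esc**2).sum(axis=0) * (euc**2).sum(axis=0))
        corr = np.where(denom > 0, (esc * euc).sum(axis=0) / denom, 0.0)
    mask = table.valid & (corr >= min_us_corr) & (
        np.nan_to_num(table.delay, nan=-np.inf) >= min_delay
    )
    report = FilterReport(
        n_input_genes=data.n_genes,
        n_after_set_intersection=data.n_genes,
        n_after_mean_filters=data.n_genes,
        n_after_correlation_delay_filters=int(mask.sum()),
        thresholds={"min_us_corr": min_us_corr, "min_delay": min_delay},
    )
    return data.subset_genes(mask), report


# ---------------------------------------------------------------------------
# fit bundles
# ---------------------------------------------------------------------------


def save_manifold_fit(fit, prefix: str | Path) -> None:
    """Write a manifold fit as NPZ plus per-cell and per-gene TSV reports."""
    prefix = Path(prefix)
    np.savez(
        prefix.with_suffix(".npz"),
        phi_xy_loc=fit.phi_xy_loc,
        nu_loc=fit.nu_loc,
        nu_scale=fit.nu_scale,
        alpha_s=fit.alpha_s,
        delta_nu=fit.delta_nu,
        elbo_trace=fit.elbo_trace,
        batch_labels=np.array([str(b) for b in fit.batch_labels]),
        gene_ids=np.array([str(g) for g in fit.gene_ids]),
    )
    draws = fit.sample_phi(n_samples=500, seed=0)
    center = fit.phi_mean
    dev = np.mod(draws - center[None, :] + np.pi, 2 * np.pi) - np.pi
    per_cell = pd.DataFrame(
        {
            "phi_mean": center,
            "phi_ci_lo": center + np.percentile(dev, 5, axis=0),
            "phi_ci_hi": center + np.percentile(dev, 95, axis=0),
        }
    )
    per_cell.to_csv(prefix.parent / (prefix.name + "_cells.tsv"), sep="\t", index=False)
    amp = np.sqrt(fit.nu_loc[:, 1] ** 2 + fit.nu_loc[:, 2] ** 2)
    per_gene = pd.DataFrame(
        {
            "gene": fit.gene_ids or np.arange(fit.nu_loc.shape[0]),
            "nu0": fit.nu_loc[:, 0],
            "nu1_cos": fit.nu_loc[:, 1],
            "nu1_sin": fit.nu_loc[:, 2],
            "nu0_sd": fit.nu_scale[:, 0],
            "peak_phase": np.mod(np.arctan2(fit.nu_loc[:, 2], fit.nu_loc[:, 1]), 2 * np.pi),
            "amplitude": amp,
        }
    )
    per_gene.to_csv(prefix.parent / (prefix.name + "_genes.tsv"), sep="\t", index=False)


def load_manifold_fit(prefix: str | Path):
    from .manifold import ManifoldFit

    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz"), allow_pickle=False) as z:
        return ManifoldFit(
            phi_xy_loc=z["phi_xy_loc"],
            nu_loc=z["nu_loc"],
            nu_scale=z["nu_scale"],
            alpha_s=z["alpha_s"],
            delta_nu=z["delta_nu"],
            elbo_trace=z["elbo_trace"],
            batch_labels=list(z["batch_labels"]),
            gene_ids=list(z["gene_ids"]),
        )


def save_velocity_fit(fit, prefix: str | Path) -> None:
    """Write a velocity fit: NPZ bundle, per-gene kinetics TSV, speed TSV."""
    prefix = Path(prefix)
    np.savez(
        prefix.with_suffix(".npz"),
        log_beta=fit.kin.log_beta,
        log_gamma=fit.kin.log_gamma,
        log_beta_sd=fit.kin_sd.log_beta,
        log_gamma_sd=fit.kin_sd.log_gamma,
        nu_omega=fit.nu_omega,
        alpha_u=fit.alpha_u,
        elbo_trace=fit.elbo_trace,
        samples_nu_omega=fit.samples.nu_omega,
        samples_log_beta=fit.samples.log_beta,
        samples_log_gamma=fit.samples.log_gamma,
    )
    pd.DataFrame(
        {
            "log_beta": fit.kin.log_beta,
            "log_gamma": fit.kin.log_gamma,
            "gamma_beta_ratio": fit.gamma_beta_ratio,
            "log_beta_sd": fit.kin_sd.log_beta,
            "log_gamma_sd": fit.kin_sd.log_gamma,
        }
    ).to_csv(prefix.parent / (prefix.name + "_kinetics.tsv"), sep="\t", index=False)
    rows = []
    for t, label in enumerate(fit.condition_labels):
        for fidx in range(fit.nu_omega.shape[1]):
            rows.append(
                {"condition": label, "coef": fidx, "value": fit.nu_omega[t, fidx]}
            )
    pd.DataFrame(rows).to_csv(
        prefix.parent / (prefix.name + "_speed.tsv"), sep="\t", index=False
    )
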
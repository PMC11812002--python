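import numpy as np
import pandas as pd
import pytest

from quantdea.annotation import SampleAnnotation
from quantdea.config import default_config
from quantdea.model import ColumnRoles, TidyQuantTable
from quantdea.pipeline import run_dea_pipeline
from quantdea.simulate import SimulationParams, simulate_experiment


def make_annotation(groups: dict[str, list[str]], subject: dict[str, str] | None = None,
                    control: str | None = None,
                    contrast_rows: list[tuple[str, str]] | None = None) -> SampleAnnotation:
    """Build a SampleAnnotation directly from a group->samples mapping."""
    rows = []
    for g, samples in groups.items():
        for s in samples:
            row = {"sample_id": s, "name": s, "group": g}
            if subject is not None:
                row["subject"] = subject[s]
            if control is not None:
                row["control"] = "C" if g == control else ""
            rows.append(row)
    return SampleAnnotation(
        table=pd.DataFrame(rows),
        has_subject=subject is not None,
        has_control=control is not None,
        contrast_rows=contrast_rows or [],
    )


def make_table(rows: list[tuple], log2: bool = False) -> TidyQuantTable:
    """rows: (sample, protein, peptide, intensity) tuples."""
    df = pd.DataFrame(rows, columns=["sample_id", "protein_id", "peptide_id", "intensity"])
    return TidyQuantTable(df, ColumnRoles(is_log_transformed=log2))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small seeded synthetic experiment written in the DIA-NN dialect."""
    out = tmp_path_factory.mktemp("sim_small")
    params = SimulationParams(n_proteins=120, n_per_group=3, seed=11)
    paths = simulate_experiment(params, out)
    return {"params": params, "dir": out, **paths}


@pytest.fixture(scope="session")
def small_dea_run(small_sim, tmp_path_factory):
    """One complete DEA run on the small fixture (shared across output tests)."""
    out = tmp_path_factory.mktemp("dea_small")
    cfg = default_config()
    run_dea_pipeline(small_sim["dir"], small_sim["annotation"], "DIANN", cfg, out)
    return {"out": out, "config": cfg, **small_sim}


@pytest.fixture(scope="session")
def recovery_sim(tmp_path_factory):
    """The parameter-recovery simulation: 2000 proteins, 5 vs 5, sigma 0.3."""
    out = tmp_path_factory.mktemp("sim_recovery")
    params = SimulationParams(
        n_proteins=2000, n_per_group=5, sigma_within=0.3,
        frac_regulated=0.1, log2fc_effect=1.0, seed=42,
    )
    paths = simulate_experiment(params, out)
    run_dir = tmp_path_factory.mktemp("dea_recovery")
    run_dea_pipeline(out, paths["annotation"], "DIANN", default_config(), run_dir)
    stats = pd.read_csv(run_dir / "results" / "DE_analysis_stats.tsv", sep="\t")
    truth = pd.read_csv(paths["truth"], sep="\t")
    return {"stats": stats, "truth": truth, "merged": stats.merge(truth, on="protein_id"),
            "out": run_dir}


def random_missing_matrix(rng: np.random.Generator, max_dim: int = 6,
                          max_missing_frac: float = 0.3) -> np.ndarray:
    nr = int(rng.integers(1, max_dim + 1))
    nc = int(rng.integers(1, max_dim + 1))
    m = rng.normal(0, 2, size=(nr, nc))
    n_missing = int(rng.integers(0, int(max_missing_frac * nr * nc) + 1))
    if n_missing:
        idx = rng.choice(nr * nc, size=n_missing, replace=False)
        m.ravel()[idx] = np.nan
    # guarantee at least one observed cell and no all-missing row/col pathologies
    if np.all(np.isnan(m)):
        m[0, 0] = rng.normal()
    return m
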
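"""Synthetic quantification experiments with known ground truth.

The generator emulates what a DIA search engine actually writes to disk — a
long-format ``report.tsv`` with q-value columns, a UniProt-style FASTA and a
sample annotation — so the parsers, filters and the whole pipeline are
exercised end to end.  The data model:

* protein baselines on the log2 scale, ``N(mu_baseline, sd_baseline)``;
* per-peptide ionization offsets, ``N(0, sd_peptide)``;
* a fixed log2 effect added to non-reference groups for a ``frac_regulated``
  subset of proteins (random sign per protein);
* i.i.d. within-group noise ``N(0, sigma_within)``;
* missing-at-low-abundance dropout: an observation at true log2 abundance x
  is missing with probability ``logistic(intercept + slope * x)``; with the
  default negative slope and the midpoint anchored at the 10th abundance
  percentile, low-abundance peptides drop out preferentially, as in real
  DIA data.

A truth table records each protein's true log2 fold change, so parameter
recovery and error control can be measured exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R appended as cleavage sites


@dataclass
class SimulationParams:
    n_proteins: int = 2000
    peptides_per_protein_mean: float = 4.0   # geometric, min 1
    n_groups: int = 2
    n_per_group: int = 5
    paired: bool = False
    frac_regulated: float = 0.1
    log2fc_effect: float = 1.0
    sigma_within: float = 0.3
    sd_baseline: float = 2.0
    mu_baseline: float = 20.0                # log2 of a typical DIA precursor intensity
    sd_peptide: float = 1.0
    sd_subject: float = 0.5
    dropout_slope: float = -1.0              # per log2 unit; <0 = missing at low abundance
    dropout_midpoint_quantile: float = 0.10
    seed: int = 0
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.frac_regulated <= 1:
            raise ValueError("frac_regulated must be in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 for estimable variance")
        if not self.group_names:
            self.group_names = (
                ["ctrl", "trt"] if self.n_groups == 2
                else [f"grp{i + 1}" for i in range(self.n_groups)]
            )


def _random_protein_sequence(rng: np.random.Generator, n_peptides: int) -> str:
    """A sequence whose tryptic digest yields plausible peptide-sized pieces."""
    parts = []
    for _ in range(max(n_peptides, 2)):
        length = int(rng.integers(5, 25))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length))
        parts.append(body + str(rng.choice(["K", "R"])))
    return "".join(parts)


def _random_peptide(rng: np.random.Generator, tag: int) -> str:
    length = int(rng.integers(7, 16))
    body = "".join(rng.choice(_AMINO_ACIDS, size=length))
    # a numeric tag keeps peptide ids unique without affecting realism of parsing
    return f"{body}{'K' if tag % 2 else 'R'}"


def _sample_layout(params: SimulationParams):
    samples, sample_group, sample_subject = [], [], []
    for g in params.group_names:
        for r in range(params.n_per_group):
            samples.append(f"run_{g}_{r + 1}.raw")
            sample_group.append(g)
            sample_subject.append(f"s{r + 1}" if params.paired else f"{g}_{r + 1}")
    return samples, sample_group, sample_subject


def simulate_experiment(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + DIA-NN-style report.tsv + annotation + truth table.

    Returns the written paths; byte-reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_prot = params.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n_prot)]
    mean_extra = max(params.peptides_per_protein_mean - 1.0, 1e-9)
    n_peptides = rng.geometric(1.0 / (1.0 + mean_extra), size=n_prot)
    n_peptides = np.maximum(n_peptides, 1)

    regulated = rng.random(n_prot) < params.frac_regulated
    signs = rng.choice([-1.0, 1.0], size=n_prot)
    true_fc = np.where(regulated, signs * params.log2fc_effect, 0.0)
    baselines = rng.normal(params.mu_baseline, params.sd_baseline, size=n_prot)

    samples, sample_group, sample_subject = _sample_layout(params)
    group_effect = {g: (0.0 if gi == 0 else 1.0) for gi, g in enumerate(params.group_names)}
    subject_shift = (
        {f"s{r + 1}": rng.normal(0, params.sd_subject) for r in range(params.n_per_group)}
        if params.paired else {}
    )

    fasta_path = out_dir / "database.fasta"
    prot_col, pep_col, prec_col, run_col, value_col = [], [], [], [], []
    pep_counter = 0
    with open(fasta_path, "w") as fh:
        for i, pid in enumerate(protein_ids):
            seq = _random_protein_sequence(rng, int(n_peptides[i]))
            fh.write(
                f">sp|{pid}|{pid}_SYNTH Synthetic protein {i} OS=Synthetic sapiens "
                f"GN=GENE{i:05d} PE=1 SV=1\n{seq}\n"
            )
            for _ in range(int(n_peptides[i])):
                pep = _random_peptide(rng, pep_counter) + f"{pep_counter:05d}".translate(
                    str.maketrans("0123456789", "ACDEFGHILM")
                )
                pep_counter += 1
                offset = rng.normal(0, params.sd_peptide)
                charge = int(rng.integers(2, 4))
                noise = rng.normal(0, params.sigma_within, size=len(samples))
                for j, sample in enumerate(samples):
                    x = (
                        baselines[i]
                        + offset
                        + true_fc[i] * group_effect[sample_group[j]]
                        + subject_shift.get(sample_subject[j], 0.0)
                        + noise[j]
                    )
                    prot_col.append(pid)
                    pep_col.append(pep)
                    prec_col.append(f"{pep}{charge}")
                    run_col.append(sample)
                    value_col.append(x)

    true_log2 = np.asarray(value_col)
    midpoint = np.quantile(true_log2, params.dropout_midpoint_quantile)
    intercept = -params.dropout_slope * midpoint
    with np.errstate(over="ignore"):
        p_missing = 1.0 / (1.0 + np.exp(-(intercept + params.dropout_slope * true_log2)))
    keep = rng.random(true_log2.size) >= p_missing

    report = pd.DataFrame(
        {
            "Run": np.asarray(run_col)[keep],
            "Protein.Group": np.asarray(prot_col)[keep],
            "Stripped.Sequence": np.asarray(pep_col)[keep],
            "Precursor.Id": np.asarray(prec_col)[keep],
            "Precursor.Quantity": np.round(np.exp2(true_log2[keep]), 4),
            "PG.Q.Value": np.round(rng.uniform(0.0, 0.009, size=int(keep.sum())), 6),
            "Q.Value": np.round(rng.uniform(0.0, 0.009, size=int(keep.sum())), 6),
        }
    )
    report_path = out_dir / "report.tsv"
    report.to_csv(report_path, sep="\t", index=False)

    ann = pd.DataFrame(
        {
            "raw.file": samples,
            "name": [s.removeprefix("run_").removesuffix(".raw") for s in samples],
            "group": sample_group,
        }
    )
    if params.paired:
        ann["subject"] = sample_subject
    ann["control"] = ["C" if g == params.group_names[0] else "" for g in sample_group]
    annotation_path = out_dir / "annotation.tsv"
    ann.to_csv(annotation_path, sep="\t", index=False)

    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "true_log2fc": true_fc,
            "regulated": regulated,
            "baseline_log2": baselines,
            "n_peptides": n_peptides,
        }
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    logger.info(
        "simulated %d proteins, %d samples, %d observations (%.1f%% dropout)",
        n_prot, len(samples), int(keep.sum()), 100 * (1 - keep.mean()),
    )
    return {
        "fasta": fasta_path,
        "report": report_path,
        "annotation": annotation_path,
        "truth": truth_path,
    }


# TMT PSM probability mixture: with mass `prob_above` the PeptideProphet
# probability is Uniform(0.9, 1), else Uniform(0.5, 0.9); purity ~ U(0.2, 1).
TMT_PROB_ABOVE = 0.8


def simulate_tmt_psm(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    """Write a FragPipe-TMT-style psm.tsv whose filter behavior is analytic.

    Expected retained fraction = P(purity >= 0.5) * P(prob > 0.9)
    = (0.5/0.8) * TMT_PROB_ABOVE.
    """
    rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_channels = params.n_groups * params.n_per_group
    channels = [f"channel_{k + 1}" for k in range(n_channels)]
    n_prot = params.n_proteins
    rows = []
    psm_id = 0
    for i in range(n_prot):
        pid = f"P{i:05d}"
        baseline = rng.normal(params.mu_baseline, params.sd_baseline)
        for _ in range(int(rng.integers(1, 4))):
            pep = _random_peptide(rng, psm_id)
            purity = rng.uniform(0.2, 1.0)
            if rng.random() < TMT_PROB_ABOVE:
                prob = rng.uniform(0.9, 1.0)
            else:
                prob = rng.uniform(0.5, 0.9)
            intensities = np.exp2(
                baseline + rng.normal(0, params.sigma_within, size=n_channels)
            )
            row = {
                "Spectrum": f"spec_{psm_id:06d}",
                "Peptide": pep,
                "Charge": int(rng.integers(2, 4)),
                "Protein": pid,
                "Purity": round(float(purity), 4),
                "PeptideProphet Probability": round(float(prob), 4),
            }
            row.update({c: round(float(v), 2) for c, v in zip(channels, intensities)})
            rows.append(row)
            psm_id += 1
    df = pd.DataFrame(rows)
    path = out_dir / "psm.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"psm": path, "channels": channels}


def expected_tmt_retained_fraction() -> float:
    """Analytic retained fraction under the simulated purity/probability laws."""
    p_purity = (1.0 - 0.5) / (1.0 - 0.2)   # P(U(0.2,1) >= 0.5)
    return p_purity * TMT_PROB_ABOVE       # P(prob > 0.9) = mixture mass above 0.9
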
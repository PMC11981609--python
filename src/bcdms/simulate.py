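"""Generative simulator for barcode-level DMS datasets.

Counts are drawn from the same process the fitting model assumes:

    count ~ NB(mu, theta),  Var = mu + mu^2/theta
    log mu = log(baseline) + condition effect + variant effect
             + barcode intercept alpha_k + sample offset gamma_m
    alpha_k ~ N(0, sigma^2), shared by barcode k across all samples

The NB is parameterized by mean and dispersion theta (the GLMM convention;
larger theta means closer to Poisson). Variant effects are supplied as a
user table on the natural-log scale; by default every nonsense variant gets
a strong loss-of-function effect in the stimulated conditions and all other
effects are zero. Per-component random streams keep count draws stable when
read simulation is added.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import mapping
from .mapping import variant_label

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the generative model.

    ``n_variants_per_position`` includes one nonsense variant per position.
    ``effect_table_truth`` maps (variant_label, condition) -> natural-log
    deviation from WT; entries absent from it default to 0 for missense and
    to ``stop_effect`` (in ``stimulated_conditions``) for nonsense variants.
    """

    n_positions: int = 4
    n_variants_per_position: int = 5
    barcodes_per_variant: int = 10
    conditions: Sequence[str] = ("DMSO_0", "aMSH_low")
    replicates_per_condition: int = 2
    sigma: float = 0.3
    theta: float = 5.0
    baseline_mean: float = 100.0
    effect_table_truth: Mapping[tuple[str, str], float] | None = None
    condition_effects: Mapping[str, float] | None = None
    stop_effect: float = -3.0
    stimulated_conditions: Sequence[str] | None = None  # default: all conditions
    offset_jitter: float = 0.1
    dropout_prob: float = 0.0
    n_wt_barcodes_per_subregion: int | None = None  # default: barcodes_per_variant
    positions_per_subregion: int | None = None  # default: one subregion
    insert_len: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.n_positions, self.n_variants_per_position,
               self.barcodes_per_variant, self.replicates_per_condition) < 1:
            raise ConfigError("all count parameters must be >= 1")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if len(self.conditions) < 1:
            raise ConfigError("at least one condition required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition labels must be unique")
        self.conditions = tuple(self.conditions)
        if self.stimulated_conditions is not None:
            self.stimulated_conditions = tuple(self.stimulated_conditions)

    @property
    def wt_barcodes(self) -> int:
        return self.n_wt_barcodes_per_subregion or self.barcodes_per_variant

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        if d["effect_table_truth"] is not None:
            d["effect_table_truth"] = {
                f"{v}\t{c}": e for (v, c), e in d["effect_table_truth"].items()
            }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("effect_table_truth") is not None:
            d["effect_table_truth"] = {
                tuple(k.split("\t")): v for k, v in d["effect_table_truth"].items()
            }
        return cls(**d)


@dataclasses.dataclass
class SimTruth:
    """Ground truth behind a simulated dataset.

    true_effects: variant x condition natural-log deviations (WT rows are 0).
    barcode_intercepts: alpha_k per surviving barcode.
    sample_offsets: gamma_m per sample (natural log).
    assignment: barcode -> variant label; oligo_assignment: barcode -> oligo.
    """

    true_effects: pd.DataFrame
    barcode_intercepts: pd.Series
    sample_offsets: pd.Series
    assignment: pd.Series
    oligo_assignment: pd.Series


def make_design(config: SimConfig) -> pd.DataFrame:
    """Build a designed-oligo table matching the configuration.

    Each position gets one nonsense oligo plus missense oligos; each
    subregion gets one synonymous (WT) oligo. Inserts are distinct random
    sequences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    per_sub = config.positions_per_subregion or config.n_positions
    rows = []
    for p in range(1, config.n_positions + 1):
        sub = f"sub{(p - 1) // per_sub + 1}"
        wt = _AA[rng.integers(len(_AA))]
        alts = ["*"]
        others = [a for a in _AA if a != wt]
        n_missense = config.n_variants_per_position - 1
        if n_missense > len(others):
            raise ConfigError("n_variants_per_position too large for 19 missense alts")
        alts += list(rng.choice(others, size=n_missense, replace=False))
        for alt in alts:
            rows.append((f"pos{p}_{alt}", p, wt, alt, sub))
    # one synonymous oligo per subregion stands in for wild-type
    for sub in sorted({r[4] for r in rows}):
        p = next(r[1] for r in rows if r[4] == sub)
        wt = next(r[2] for r in rows if r[4] == sub)
        rows.append((f"WT_{sub}", p, wt, wt, sub))
    design = pd.DataFrame(rows, columns=["oligo_id", "position", "wt_aa", "alt_aa", "subregion"])
    seen: set[str] = set()
    inserts = []
    for _ in range(len(design)):
        while True:
            s = "".join(_NT[rng.integers(0, 4, size=config.insert_len)])
            if s not in seen:
                seen.add(s)
                inserts.append(s)
                break
    design["insert_seq"] = inserts
    return mapping.validate_design(design[mapping.DESIGN_COLUMNS])


def _random_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(_NT[rng.integers(0, 4, size=mapping.BARCODE_LEN)])
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def true_effect_frame(config: SimConfig, design: pd.DataFrame) -> pd.DataFrame:
    """Variant x condition matrix of true natural-log deviations from WT."""
    labels = mapping.design_variant_labels(design)
    variants = ["WT"] + sorted(set(labels) - {"WT"})
    eff = pd.DataFrame(0.0, index=variants, columns=list(config.conditions))
    stim = (
        set(config.stimulated_conditions)
        if config.stimulated_conditions is not None
        else set(config.conditions)
    )
    nonsense = labels[design["alt_aa"] == "*"]
    for v in nonsense:
        for c in stim:
            eff.loc[v, c] = config.stop_effect
    if config.effect_table_truth:
        for (v, c), e in config.effect_table_truth.items():
            if v == "WT" and e != 0:
                raise ConfigError("WT true effect must be 0")
            if v in eff.index and c in eff.columns:
                eff.loc[v, c] = e
    eff.loc["WT"] = 0.0
    return eff


def simulate_counts(
    config: SimConfig, design: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw a barcode x sample count table from the generative model.

    Returns (counts, sample_sheet, truth). ``counts`` carries barcode
    annotation columns followed by one integer column per sample; every
    (barcode, sample) cell is populated (zeros are explicit). The sample
    sheet has sample_id/condition/replicate/offset, with the true technical
    offsets gamma_m in the offset column.
    """
    if design is None:
        design = make_design(config)
    ss = np.random.SeedSequence([config.seed, 17])
    rng_struct, rng_counts = [np.random.default_rng(s) for s in ss.spawn(2)]

    # barcode -> oligo assignment, with whole-barcode dropout
    oligo_rows = []
    for _, row in design.iterrows():
        n = (
            config.wt_barcodes
            if row["alt_aa"] == row["wt_aa"]
            else config.barcodes_per_variant
        )
        oligo_rows += [row] * n
    barcodes = _random_barcodes(len(oligo_rows), rng_struct)
    keep = rng_struct.random(len(barcodes)) >= config.dropout_prob
    if not keep.any():
        keep[0] = True
    bc_design = pd.DataFrame([r.to_dict() for r in oligo_rows])
    bc_design["barcode"] = barcodes
    bc_design = bc_design[keep].reset_index(drop=True)
    n_bc = len(bc_design)

    labels = mapping.design_variant_labels(bc_design)
    bc_design["variant"] = labels.to_numpy()

    samples = [
        (f"{cond}_r{r}", cond, r)
        for cond in config.conditions
        for r in range(1, config.replicates_per_condition + 1)
    ]
    sample_sheet = pd.DataFrame(samples, columns=["sample_id", "condition", "replicate"])
    gamma = rng_struct.normal(0.0, config.offset_jitter, size=len(sample_sheet))
    sample_sheet["offset"] = gamma

    alpha = rng_struct.normal(0.0, config.sigma, size=n_bc)
    eff = true_effect_frame(config, design)
    cond_eff = {c: 0.0 for c in config.conditions}
    if config.condition_effects:
        cond_eff.update(config.condition_effects)

    counts = bc_design[
        ["barcode", "oligo_id", "position", "wt_aa", "alt_aa", "subregion", "variant"]
    ].copy()
    var_eff = eff.loc[bc_design["variant"]]  # n_bc x n_cond
    log_base = np.log(config.baseline_mean)
    for m, (sid, cond, _rep) in enumerate(samples):
        log_mu = (
            log_base + cond_eff[cond] + var_eff[cond].to_numpy() + alpha + gamma[m]
        )
        mu = np.exp(log_mu)
        if config.theta > 1e8:  # Poisson limit, avoids NB numeric issues
            counts[sid] = rng_counts.poisson(mu)
        else:
            p = config.theta / (config.theta + mu)
            counts[sid] = rng_counts.negative_binomial(config.theta, p)

    truth = SimTruth(
        true_effects=eff,
        barcode_intercepts=pd.Series(alpha, index=counts["barcode"].to_numpy()),
        sample_offsets=pd.Series(gamma, index=sample_sheet["sample_id"].to_numpy()),
        assignment=pd.Series(
            counts["variant"].to_numpy(), index=counts["barcode"].to_numpy()
        ),
        oligo_assignment=pd.Series(
            counts["oligo_id"].to_numpy(), index=counts["barcode"].to_numpy()
        ),
    )
    return counts, sample_sheet, truth


# ---------------------------------------------------------------------------
# read-level simulation


def simulate_reads(
    truth: SimTruth,
    design: pd.DataFrame,
    n_reads: int,
    chimera_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Emit mapping-style reads: 21-nt barcode followed by the oligo insert.

    With probability ``chimera_rate`` a read's insert is swapped for a
    different oligo's insert (an impure pairing); substitution errors are
    applied per base at ``error_rate``. Returns (read_id, sequence) pairs.
    """
    if not 0 <= chimera_rate < 1 or not 0 <= error_rate < 1:
        raise ConfigError("chimera_rate and error_rate must be in [0, 1)")
    if design.empty:
        raise ConfigError("empty design")
    mapping.validate_design(design)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    barcodes = truth.oligo_assignment.index.to_numpy()
    oligos = truth.oligo_assignment.to_numpy()
    inserts = design.set_index("oligo_id")["insert_seq"]
    all_oligos = design["oligo_id"].to_numpy()

    picks = rng.integers(0, len(barcodes), size=n_reads)
    chim = rng.random(n_reads) < chimera_rate
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        bc = barcodes[picks[i]]
        oligo = oligos[picks[i]]
        if chim[i] and len(all_oligos) > 1:
            while True:
                other = all_oligos[rng.integers(0, len(all_oligos))]
                if other != oligo:
                    oligo = other
                    break
        seq = bc + inserts[oligo]
        if error_rate > 0:
            arr = np.array(list(seq))
            hit = rng.random(len(arr)) < error_rate
            if hit.any():
                arr[hit] = _NT[(np.searchsorted(_NT, arr[hit]) + rng.integers(1, 4, size=hit.sum())) % 4]
                seq = "".join(arr)
        reads.append((f"read{i}", seq))
    return reads


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (id, seq) pairs as 4-line FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_sample_sheet(sample_sheet: pd.DataFrame, path) -> None:
    sample_sheet.to_csv(path, sep="\t", index=False)


def write_truth(truth: SimTruth, prefix) -> None:
    """Write ground-truth tables as TSV files sharing a path prefix."""
    truth.true_effects.rename_axis("variant").to_csv(f"{prefix}.effects.tsv", sep="\t")
    pd.DataFrame(
        {
            "barcode": truth.assignment.index,
            "variant": truth.assignment.to_numpy(),
            "oligo_id": truth.oligo_assignment.to_numpy(),
            "alpha": truth.barcode_intercepts.to_numpy(),
        }
    ).to_csv(f"{prefix}.barcodes.tsv", sep="\t", index=False)
    truth.sample_offsets.rename_axis("sample_id").rename("gamma").to_csv(
        f"{prefix}.offsets.tsv", sep="\t"
    )
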
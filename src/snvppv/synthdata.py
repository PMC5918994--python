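"""Synthetic training tables and toy VCF truth/call fixtures.

The table generator draws call-set covariates in realistic human
ranges (Ti/Tv in 1-3.5, Het/Hom in 1-7, median depth 5-150, DpLt5 in
0-0.5, a WES/WGS mix), forms the centered design exactly as the design
module does, and draws TP counts Y Beta-binomially through the logit
mean and log dispersion links — i.e. data with precisely the
statistical structure the regression assumes. Default coefficient
vectors reproduce the (11, 6) model fitted to human NA12878 WES/WGS
gold-standard call sets, so the default tables stand in for the ~500
gold-standard-derived observations such a study produces.

The VCF-pair generator fabricates a truth set and a call set that is
the truth plus a controlled number of false-positive records, giving a
validation fixture with exactly known TP/FP and target Ti/Tv values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .betabinom import link_sigma
from .design import ModelSpec, build_design, named_spec
from .vcf_io import Region, VariantRecord

__all__ = [
    "SimulationConfig",
    "default_config",
    "simulate_training_table",
    "simulate_vcf_pair",
    "write_vcf",
    "write_bed",
]

# (11, 6) coefficients on the centered scale: mean part over
# (1, wes, titv, med_dp, dp_lt5, titv^2, med_dp^2, wes:titv,
#  wes:med_dp, wes:dp_lt5, titv:med_dp), dispersion part over
# (1, wes, titv, dp_lt5, titv^2, wes:titv).
DEFAULT_BETA = (
    5.02,
    -1.42,
    5.15,
    -1.96e-2,
    -1.79,
    -1.75e-1,
    -1.40e-4,
    -4.47,
    4.72e-2,
    1.76,
    -1.91e-2,
)
DEFAULT_GAMMA = (-6.81047, 3.00998, -10.04787, -0.33822, -6.32795, 9.01236)

DEFAULT_RANGES = {
    "titv": (1.0, 3.5),
    "hethom": (1.0, 7.0),
    "med_dp": (5.0, 150.0),
    "dp_lt5": (0.0, 0.5),
}


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic training table."""

    n_obs: int = 500
    spec: ModelSpec = field(default_factory=lambda: named_spec("m11_6"))
    beta: Sequence[float] = DEFAULT_BETA
    gamma: Sequence[float] = DEFAULT_GAMMA
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    wes_prob: float = 0.5
    n_range: tuple[int, int] = (10_000, 100_000)  # log-uniform call-list sizes
    titv_hethom_corr: float = 0.0  # in [0, 1): rank-coupled negative association
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be positive")
        for cov, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {cov!r}")
        if not 0 <= self.titv_hethom_corr < 1:
            raise ValueError("titv_hethom_corr must lie in [0, 1)")
        if len(self.beta) != self.spec.p or len(self.gamma) != self.spec.q:
            raise ValueError(
                f"coefficient lengths ({len(self.beta)}, {len(self.gamma)}) "
                f"do not match spec ({self.spec.p}, {self.spec.q})"
            )


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def simulate_training_table(config: SimulationConfig) -> pd.DataFrame:
    """Draw a training table (raw covariates + Y, N) from the model.

    Covariates are independent uniforms over their ranges (optionally a
    rank coupling induces the negative Ti/Tv vs Het/Hom association
    seen in real call sets); Y is drawn Beta(alpha, beta)-then-Binomial,
    which is the exact Beta-binomial composition. The table's own
    covariate means define the centering, matching how a real table
    would be processed. Any mu that exits (0, 1) numerically is clamped
    and counted in ``df.attrs['n_mu_clamped']``.
    """
    rng = np.random.default_rng(config.seed)
    n_obs = config.n_obs
    u_titv = rng.uniform(size=n_obs)
    c = config.titv_hethom_corr
    u_hethom = c * (1.0 - u_titv) + (1.0 - c) * rng.uniform(size=n_obs)

    def scale(u, cov):
        lo, hi = config.ranges[cov]
        return lo + (hi - lo) * u

    table = pd.DataFrame(
        {
            "titv": scale(u_titv, "titv"),
            "hethom": scale(u_hethom, "hethom"),
            "med_dp": scale(rng.uniform(size=n_obs), "med_dp"),
            "dp_lt5": scale(rng.uniform(size=n_obs), "dp_lt5"),
            "wes_indicator": rng.binomial(1, config.wes_prob, size=n_obs),
        }
    )
    lo_n, hi_n = config.n_range
    n = np.exp(rng.uniform(np.log(lo_n), np.log(hi_n), size=n_obs)).astype(int)

    dm = build_design(table, config.spec)
    eta = dm.X @ np.asarray(config.beta, dtype=float)
    mu = expit(eta)
    n_clamped = int(np.sum((mu <= 1e-9) | (mu >= 1.0 - 1e-9)))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} simulated mu values clamped away from {{0, 1}}",
            RuntimeWarning,
            stacklevel=2,
        )
    mu = np.clip(mu, 1e-9, 1.0 - 1e-9)
    sigma = np.asarray(
        link_sigma(
            dm.Z @ np.asarray(config.gamma, dtype=float),
            config.spec.dispersion_link,
            config.spec.boxcox_lambda,
        )
    )

    p_success = np.where(
        sigma > 1e-12,
        rng.beta(np.maximum(mu / np.maximum(sigma, 1e-300), 1e-12),
                 np.maximum((1.0 - mu) / np.maximum(sigma, 1e-300), 1e-12)),
        mu,
    )
    y = rng.binomial(n, p_success)

    out = table.copy()
    out.insert(0, "n", n)
    out.insert(0, "y", y)
    out.attrs["n_mu_clamped"] = n_clamped
    # tuples, not arrays: DataFrame.attrs must stay comparable under ==
    out.attrs["true_mu"] = tuple(float(v) for v in mu)
    out.attrs["true_sigma"] = tuple(float(v) for v in sigma)
    return out


_TRANSITION_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_TRANSVERSION_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
]


def _make_records(
    positions: np.ndarray,
    titv: float,
    het_fraction: float,
    depth_mean: float,
    qual_range: tuple[float, float],
    rng: np.random.Generator,
    contig: str,
) -> list[VariantRecord]:
    n = len(positions)
    n_ti = int(round(n * titv / (1.0 + titv)))
    is_ti = np.zeros(n, dtype=bool)
    is_ti[:n_ti] = True
    rng.shuffle(is_ti)
    recs = []
    for pos, ti in zip(positions, is_ti):
        pairs = _TRANSITION_PAIRS if ti else _TRANSVERSION_PAIRS
        ref, alt = pairs[rng.integers(len(pairs))]
        recs.append(
            VariantRecord(
                contig=contig,
                pos=int(pos),
                ref=ref,
                alt=alt,
                genotype="het" if rng.uniform() < het_fraction else "hom_alt",
                qual=float(rng.uniform(*qual_range)),
                depth=int(rng.poisson(depth_mean)),
            )
        )
    return recs


def simulate_vcf_pair(
    n_true: int,
    n_false: int,
    titv_true: float = 2.5,
    titv_false: float = 0.5,
    depth_mean: float = 30.0,
    seed: int = 0,
    *,
    het_fraction: float = 2.0 / 3.0,
    contig: str = "chr1",
) -> tuple[list[VariantRecord], list[VariantRecord], list[Region]]:
    """Fabricate (truth records, call records, confident regions).

    The call set is the truth set plus ``n_false`` false positives at
    disjoint positions, so validating the pair yields exactly
    (tp=n_true, fp=n_false). True calls target Ti/Tv ``titv_true``;
    false calls target the random-substitution-like ``titv_false``,
    mimicking how false positives depress a call set's Ti/Tv.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("counts must be non-negative")
    if n_true + n_false == 0:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    window = 50 * (n_true + n_false) + 1000
    positions = rng.choice(np.arange(1, window + 1), size=n_true + n_false, replace=False)
    positions.sort()
    which_true = np.zeros(n_true + n_false, dtype=bool)
    which_true[rng.choice(n_true + n_false, size=n_true, replace=False)] = True

    truth = _make_records(
        positions[which_true], titv_true, het_fraction, depth_mean, (40.0, 200.0), rng, contig
    )
    false_calls = _make_records(
        positions[~which_true], titv_false, het_fraction, depth_mean, (1.0, 60.0), rng, contig
    )
    calls = sorted(truth + false_calls, key=lambda r: r.pos)
    confident = [Region(contig, 0, window + 100)]
    return truth, calls, confident


_GT_FIELD = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0", "missing": "./."}


def write_vcf(records: Sequence[VariantRecord], path, sample: str = "SYNTH") -> None:
    """Write records as a minimal single-sample VCF v4.2 text file."""
    contigs = sorted({r.contig for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snvppv-synthetic\n")
        for c in contigs:
            length = max(r.pos for r in records if r.contig == c) + 1000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for r in sorted(records, key=lambda x: (x.contig, x.pos)):
            fh.write(
                f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.2f}\t.\t.\t"
                f"GT:DP\t{_GT_FIELD[r.genotype]}:{r.depth}\n"
            )


def write_bed(regions: Sequence[Region], path) -> None:
    with open(path, "w") as fh:
        for reg in sorted(regions):
            fh.write(f"{reg.contig}\t{reg.start}\t{reg.end}\n")
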
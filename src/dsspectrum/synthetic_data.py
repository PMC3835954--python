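"""Synthetic inputs with the statistical structure the analysis assumes.

The study's ortholog sequences and raw bioassay counts are unpublished, so
fixtures are generated: 240-nt ortholog families with SNPs planted at
controlled positions (including solving for an exact shared 21-mer window
count, the quantity that depends on SNP *location* and not just count), and
binomial dose-response data drawn from the natural-response probit model.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedPair
from .bioassay_stats import DoseResponseData, TwoGroupCounts
from .errors import InfeasibleError, ValidationError
from .match_stats import DEFAULT_K, shared_window_count
from .seq_io import SequenceRecord

BASES = "ACGT"


@dataclass(frozen=True)
class OrthologSpec:
    """Recipe for one synthetic ortholog: length, SNPs, optional target m."""

    length: int = 240
    snp_count: int | None = None
    snp_positions: tuple[int, ...] | None = None
    target_m: int | None = None
    k: int = DEFAULT_K
    seed: int = 0

    def __post_init__(self):
        if self.snp_positions is not None:
            pos = self.snp_positions
            if len(set(pos)) != len(pos):
                raise ValidationError("duplicate SNP positions")
            if any(not 1 <= p <= self.length for p in pos):
                raise ValidationError("SNP position outside [1, L]")

    @property
    def s(self) -> int:
        if self.snp_positions is not None:
            return len(self.snp_positions)
        return self.snp_count or 0


@dataclass(frozen=True)
class BioassaySpec:
    """Probit parameters plus the dose design of a feeding bioassay.

    Defaults mirror a conspecific dose-response design for a sensitive
    beetle: 8 twofold-spaced concentrations from 1.6 ng/mL diet, 16 insects
    per concentration, slope 1.6 per log10 dose, LC50 19 ng/mL, 5% natural
    mortality.
    """

    b: float = 1.6
    lc50: float = 19.0
    c: float = 0.05
    dose_start: float = 1.6
    dose_factor: float = 2.0
    n_doses: int = 8
    n_per_dose: int = 16
    control_n: int = 16
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.dose_start <= 0 or self.dose_factor <= 1:
            raise ValidationError("doses must be positive with factor > 1")
        if not 0 <= self.c < 1:
            raise ValidationError("natural mortality c must lie in [0, 1)")

    @property
    def a(self) -> float:
        """Intercept implied by (slope, lc50): lc50 = 10^(-a/b)."""
        return -self.b * np.log10(self.lc50)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(
            self.dose_start * self.dose_factor**i for i in range(self.n_doses)
        )


def random_trigger(length: int = 240, seed: int = 0, id: str = "trigger") -> SequenceRecord:
    """Uniform random DNA sequence over {A,C,G,T}, reproducible under seed."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(BASES), size=length))
    return SequenceRecord(id=id, residues=residues, description="synthetic trigger")


def mutate_with_snps(
    trigger: SequenceRecord,
    positions: tuple[int, ...] | list[int],
    seed: int = 0,
    id: str | None = None,
) -> SequenceRecord:
    """Copy the trigger with a substitution at each 1-based position.

    Each planted base is drawn uniformly from the three alternatives, so the
    trivial (gap-free) alignment has exactly ``len(positions)`` SNPs.
    """
    positions = tuple(positions)
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate SNP positions")
    if any(not 1 <= p <= len(trigger) for p in positions):
        raise ValidationError("SNP position outside the sequence")
    rng = np.random.default_rng(seed)
    residues = list(trigger.residues)
    for p in sorted(positions):
        old = residues[p - 1]
        choices = [b for b in BASES if b != old]
        residues[p - 1] = choices[rng.integers(len(choices))]
    return SequenceRecord(
        id=id or f"{trigger.id}_snp{len(positions)}",
        residues="".join(residues),
        description=f"synthetic ortholog with {len(positions)} planted SNPs",
    )


def window_count_bounds(length: int, s: int, k: int = DEFAULT_K) -> tuple[int, int]:
    """Attainable [min, max] shared k-window count for s SNPs in a gap-free pair.

    W = L - k + 1 windows exist; clustering the SNPs at one end destroys the
    fewest (max m = W - min(s, W)); spacing them k apart destroys the most
    (min m = max(0, W - s*k)).
    """
    W = length - k + 1
    return max(0, W - s * k), W - min(s, W)


def place_snps_for_window_count(spec: OrthologSpec) -> tuple[int, ...]:
    """Choose s SNP positions realizing an exact shared k-window count.

    Construction: keep one clean run of target_m + k - 1 columns at the left
    end, start the tail with a SNP, and break the rest of the tail with SNPs
    spaced k apart so no clean run of length k survives; spare SNPs fill
    remaining tail positions (order shuffled under the seed). The placement
    is verified against the brute-force window scan before being returned.
    """
    L, k, s, m = spec.length, spec.k, spec.s, spec.target_m
    if m is None:
        raise ValidationError("spec.target_m is required")
    W = L - k + 1
    lo, hi = window_count_bounds(L, s, k)
    if not lo <= m <= hi:
        raise InfeasibleError(
            f"target_m={m} unattainable with s={s} SNPs at L={L}, k={k}; "
            f"attainable range is [{lo}, {hi}]"
        )

    if m == 0:
        mandatory = list(range(k, L + 1, k))  # hits every window
    else:
        tail_start = m + k  # first position after the protected clean run
        mandatory = list(range(tail_start, L + 1, k))
    if len(mandatory) > s:
        # feasibility guaranteed above; trim is impossible by construction
        raise InfeasibleError("internal: mandatory SNPs exceed s")  # pragma: no cover

    protected_end = 0 if m == 0 else m + k - 1
    spare_pool = [
        p for p in range(protected_end + 1, L + 1) if p not in set(mandatory)
    ]
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(spare_pool)
    positions = tuple(sorted(mandatory + spare_pool[: s - len(mandatory)]))
    if len(positions) != s:  # pragma: no cover
        raise InfeasibleError("internal: could not place all SNPs")

    # mandatory oracle check: never return an unverified placement
    trigger = "A" * L
    other = list(trigger)
    for p in positions:
        other[p - 1] = "C"
    profile = shared_window_count(
        AlignedPair(row_a=trigger, row_b="".join(other)), k=k
    )
    if profile.m != m:  # pragma: no cover
        raise InfeasibleError(
            f"internal: placement yields m={profile.m}, wanted {m}"
        )
    return positions


def synthetic_ortholog(trigger: SequenceRecord, spec: OrthologSpec, id: str | None = None) -> SequenceRecord:
    """Generate an ortholog from the trigger per an OrthologSpec."""
    if spec.length != len(trigger):
        raise ValidationError("spec.length must match the trigger length")
    if spec.snp_positions is not None:
        positions = spec.snp_positions
    elif spec.target_m is not None:
        positions = place_snps_for_window_count(spec)
    else:
        rng = np.random.default_rng(spec.seed)
        positions = tuple(
            sorted(rng.choice(np.arange(1, spec.length + 1), size=spec.s, replace=False))
        )
    return mutate_with_snps(trigger, positions, seed=spec.seed + 1, id=id)


def simulate_dose_response(spec: BioassaySpec) -> list[DoseResponseData]:
    """Draw binomial mortality from the natural-response probit model.

    Returns one DoseResponseData per replicate; each includes a dose-0
    control group of ``control_n`` insects dying at rate c.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(spec.seed)
    doses = np.array(spec.doses)
    p = spec.c + (1 - spec.c) * norm.cdf(spec.a + spec.b * np.log10(doses))
    out = []
    for _ in range(spec.replicates):
        dead = rng.binomial(spec.n_per_dose, p)
        ctrl_dead = rng.binomial(spec.control_n, spec.c) if spec.control_n else 0
        out.append(
            DoseResponseData(
                doses=tuple(float(d) for d in doses),
                n_exposed=(spec.n_per_dose,) * spec.n_doses,
                n_dead=tuple(int(x) for x in dead),
                control_n=spec.control_n,
                control_dead=int(ctrl_dead),
            )
        )
    return out


def simulate_survival_table(
    p_control: float,
    p_treat: float,
    n_control: int,
    n_treat: int,
    seed: int = 0,
    labels: tuple[str, str] = ("control", "test"),
) -> TwoGroupCounts:
    """Binomial survival draws for a single-concentration two-group assay.

    ``p_control``/``p_treat`` are survival probabilities; the returned
    counts record deaths (events)."""
    for p in (p_control, p_treat):
        if not 0 <= p <= 1:
            raise ValidationError("survival proportions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dead_c = int(rng.binomial(n_control, 1 - p_control))
    dead_t = int(rng.binomial(n_treat, 1 - p_treat))
    return TwoGroupCounts(
        labels=labels, n_total=(n_control, n_treat), n_event=(dead_c, dead_t)
    )
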
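"""Marker-based species profiling, diversity, and species-level engraftment rules.

Reads are assigned to species through species-specific marker k-mers (a
clade-marker profiler in miniature): each read matching at least one
marker k-mer is attributed to that marker's species, and relative
abundances are percentages over assigned reads. On top of the profiles
sit the Shannon diversity index, the transplanted-species rule (a species
undetectable in both recipient baselines, carried by the donor, rising to
at least 0.2% after transplant), large-change flags (absolute change above
5 percentage points; log10 change of one log or more), and a paired
donor-vs-recipient species test with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._kmers import kmer_set
from .synthetic_data import POST_TIMEPOINTS, MarkerDatabase, SampleLibrary


@dataclass
class TaxonomyConfig:
    """Thresholds for the species-level rules.

    ``min_transplant_gain``: the post-transplant relative abundance (percent)
    a baseline-undetectable donor species must reach to count as
    transplanted. ``large_change_abs``: absolute-change flag threshold in
    percentage points. ``log_change_threshold``: log10 fold-change flag
    threshold. ``detection_floor``: abundances at or below this percent are
    treated as undetectable (0 = exactly absent).
    """

    min_transplant_gain: float = 0.2
    large_change_abs: float = 5.0
    log_change_threshold: float = 1.0
    detection_floor: float = 0.0
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(
            self.min_transplant_gain,
            self.large_change_abs,
            self.log_change_threshold,
            self.detection_floor,
            self.fdr_alpha,
        ) < 0:
            raise ValueError("all thresholds must be >= 0")


@dataclass
class AbundanceProfile:
    """Per-sample species relative abundances in percent (summing to 100)."""

    sample_id: str
    abundances: dict[str, float] = field(default_factory=dict)
    n_assigned_reads: int = 0

    def __post_init__(self) -> None:
        if self.n_assigned_reads > 0:
            total = sum(self.abundances.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"abundances sum to {total}, expected 100")
            if any(v < 0 for v in self.abundances.values()):
                raise ValueError("abundances must be non-negative")

    def get(self, species: str) -> float:
        """Abundance in percent; species absent from the map are 0 (undetectable)."""
        return self.abundances.get(species, 0.0)

    @property
    def species(self) -> list[str]:
        return list(self.abundances)


class MarkerCollisionError(RuntimeError):
    """A read matched markers of more than one species, violating uniqueness."""


def profile_abundance(
    library: SampleLibrary,
    marker_db: MarkerDatabase,
    kmer_length: int | None = None,
) -> AbundanceProfile:
    """Assign reads to species via marker k-mers and tabulate relative abundance.

    A read is attributed to the unique species with which it shares at
    least one canonical marker k-mer; reads matching no marker are left
    unassigned and excluded from the denominator. A read matching two
    species' markers violates the marker-uniqueness construction and raises
    :class:`MarkerCollisionError`. A library with zero assigned reads
    yields an empty profile (``n_assigned_reads == 0``), flagged
    unevaluable by downstream consumers.
    """
    k = kmer_length or marker_db.kmer_length
    if k > marker_db.marker_length:
        raise ValueError(
            f"profiler k-mer length {k} exceeds marker length {marker_db.marker_length}"
        )
    kmer_to_species: dict[str, str] = {}
    for sid, markers in marker_db.markers.items():
        for marker in markers:
            for km in kmer_set(marker, k):
                other = kmer_to_species.get(km)
                if other is not None and other != sid:
                    raise MarkerCollisionError(
                        f"marker k-mer shared by {other} and {sid}"
                    )
                kmer_to_species[km] = sid

    counts: dict[str, int] = {}
    for read in library.reads:
        hits = {
            kmer_to_species[km]
            for km in kmer_set(read.sequence, k)
            if km in kmer_to_species
        }
        if len(hits) > 1:
            raise MarkerCollisionError(
                f"read {read.read_id} matches markers of multiple species: {sorted(hits)}"
            )
        if hits:
            sid = hits.pop()
            counts[sid] = counts.get(sid, 0) + 1

    n_assigned = sum(counts.values())
    abundances = (
        {sid: 100.0 * c / n_assigned for sid, c in sorted(counts.items())}
        if n_assigned
        else {}
    )
    return AbundanceProfile(
        sample_id=library.sample_id, abundances=abundances, n_assigned_reads=n_assigned
    )


def shannon_index(profile: AbundanceProfile | Mapping[str, float], base: float | None = None) -> float:
    """Shannon(-Weiner) diversity H = -sum p_i log p_i over detected species.

    Natural log by default (nats); pass ``base`` for other units. Raises on
    an empty profile, where diversity is undefined.
    """
    abundances = profile.abundances if isinstance(profile, AbundanceProfile) else dict(profile)
    ps = [v / 100.0 for v in abundances.values() if v > 0]
    if not ps:
        raise ValueError("Shannon index undefined for an empty profile")
    h = -sum(p * math.log(p) for p in ps) + 0.0  # +0.0 normalizes -0.0
    return h / math.log(base) if base else h


@dataclass
class TransplantCall:
    """One species' evaluation under the transplanted-species rule."""

    species: str
    recipient_id: str
    donor_abundance: float
    baseline_abundances: dict[str, float]
    post_abundances: dict[str, float]
    qualifies: bool
    call: str | None = None  # transient | persistent | late (when qualifies)


def detect_transplanted_species(
    recipient_profiles_by_timepoint: Mapping[str, AbundanceProfile],
    donor_profile: AbundanceProfile,
    config: TaxonomyConfig | None = None,
    *,
    recipient_id: str = "",
) -> list[TransplantCall]:
    """Apply the transplanted-species rule to every donor-carried species.

    A species qualifies when it is undetectable (<= detection floor) in
    BOTH recipient baselines (BL1 and BL2), present in the donor (> floor),
    and reaches at least ``min_transplant_gain`` percent at one or more
    post-transplant timepoints. Qualifying species are subtyped by when
    they appear: *persistent* (at every observed post timepoint),
    *late* (first appearance at 1 month or later), otherwise *transient*
    (present early but lost).
    """
    config = config or TaxonomyConfig()
    for bl in ("BL1", "BL2"):
        if bl not in recipient_profiles_by_timepoint:
            raise ValueError(f"recipient baseline {bl} profile missing")
    baselines = {bl: recipient_profiles_by_timepoint[bl] for bl in ("BL1", "BL2")}
    post_labels = [l for l in POST_TIMEPOINTS if l in recipient_profiles_by_timepoint]

    calls: list[TransplantCall] = []
    for species, donor_ab in sorted(donor_profile.abundances.items()):
        if donor_ab <= config.detection_floor:
            continue
        base_abs = {bl: p.get(species) for bl, p in baselines.items()}
        post_abs = {
            l: recipient_profiles_by_timepoint[l].get(species) for l in post_labels
        }
        undetectable = all(v <= config.detection_floor for v in base_abs.values())
        hits = [l for l, v in post_abs.items() if v >= config.min_transplant_gain]
        qualifies = undetectable and bool(hits)
        call = None
        if qualifies:
            if len(hits) == len(post_labels):
                call = "persistent"
            elif hits[0] != post_labels[0]:
                call = "late"
            else:
                call = "transient"
        calls.append(
            TransplantCall(
                species=species,
                recipient_id=recipient_id,
                donor_abundance=donor_ab,
                baseline_abundances=base_abs,
                post_abundances=post_abs,
                qualifies=qualifies,
                call=call,
            )
        )
    return calls


def detect_large_changes(
    pre_profile: AbundanceProfile,
    post_profile: AbundanceProfile,
    config: TaxonomyConfig | None = None,
) -> pd.DataFrame:
    """Per-species absolute and log10 changes between two profiles.

    The species universe is the union of the two profiles (missing = 0).
    ``log_change`` is defined only when both abundances are positive;
    appearances/disappearances are flagged ``from_zero``/``to_zero``
    rather than pseudocounted. Flags: ``large_abs`` when the absolute
    change exceeds ``large_change_abs`` percentage points; ``log_flag``
    when |log10 change| is at least ``log_change_threshold``.
    """
    config = config or TaxonomyConfig()
    rows = []
    for species in sorted(set(pre_profile.species) | set(post_profile.species)):
        pre = pre_profile.get(species)
        post = post_profile.get(species)
        abs_change = abs(post - pre)
        log_change = math.log10(post / pre) if pre > 0 and post > 0 else math.nan
        rows.append(
            {
                "species": species,
                "pre": pre,
                "post": post,
                "abs_change": abs_change,
                "log_change": log_change,
                "from_zero": pre == 0 and post > 0,
                "to_zero": post == 0 and pre > 0,
                "large_abs": abs_change > config.large_change_abs,
                "log_flag": (not math.isnan(log_change))
                and abs(log_change) >= config.log_change_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "pre", "post", "abs_change", "log_change",
            "from_zero", "to_zero", "large_abs", "log_flag",
        ],
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (statsmodels-backed)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def donor_recipient_species_test(
    donor_profiles: Sequence[AbundanceProfile],
    paired_recipient_profiles: Sequence[AbundanceProfile],
    config: TaxonomyConfig | None = None,
) -> pd.DataFrame:
    """Paired two-tailed t-test per species across donor/recipient pairs.

    Profiles must be aligned (pair i = donor i vs recipient i, at least 2
    pairs). Each species present in at least one sample is tested on its
    relative abundances; p-values from pairs with zero difference variance
    are set to 1 by convention. Benjamini-Hochberg q-values are attached:
    ``significant`` marks q < alpha, ``nominal_only`` marks p < 0.05 that
    does not survive correction.
    """
    config = config or TaxonomyConfig()
    if len(donor_profiles) != len(paired_recipient_profiles):
        raise ValueError("donor and recipient profile lists must be paired")
    if len(donor_profiles) < 2:
        raise ValueError("need at least 2 donor/recipient pairs")

    universe = sorted(
        {s for p in (*donor_profiles, *paired_recipient_profiles) for s in p.species}
    )
    rows = []
    for species in universe:
        d = np.array([p.get(species) for p in donor_profiles])
        r = np.array([p.get(species) for p in paired_recipient_profiles])
        diffs = d - r
        if np.allclose(diffs, diffs[0]):
            # zero variance in the paired differences: the t statistic is
            # undefined. All-zero differences carry no evidence (p = 1);
            # a constant nonzero difference is a perfectly consistent
            # effect and is reported as p = 0 with an infinite statistic.
            if np.allclose(diffs[0], 0.0):
                t_stat, p_val = math.nan, 1.0
            else:
                t_stat, p_val = math.copysign(math.inf, diffs[0]), 0.0
        else:
            t_stat, p_val = stats.ttest_rel(d, r)
        rows.append({"species": species, "mean_donor": d.mean(), "mean_recipient": r.mean(),
                     "t": t_stat, "p": p_val})
    df = pd.DataFrame(rows)
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["significant"] = df["q"] < config.fdr_alpha
    df["nominal_only"] = (df["p"] < 0.05) & ~df["significant"]
    return df
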
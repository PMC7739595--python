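"""Synthetic longitudinal athlete cohorts with a known dependency structure.

The generator produces the same table layout as the study design it
emulates: recruited participants measured at three in-person time
points (T1-T3) plus a remote injury report (T4), with a configurable
number of participants dropping out after T1.  All dependencies are
explicit in :class:`GroundTruthModel`, so downstream learning and
inference can be validated against a known answer.

Injury in each reporting interval follows a logistic model whose
linear predictor combines the within-interval *changes* in muscle
stiffness and negative life events (scaled by ``effect_scale``) with
the stiffness level at the interval start.  ``effect_scale = 0``
renders injury independent of everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stressnet.bn.dag import Dag
from stressnet.measures import IbiSeries

TIME_POINTS = ("T1", "T2", "T3")
MEASURE_COLUMNS = (
    "training_hours",
    "nle",
    "ple",
    "tle",
    "bis",
    "fffs",
    "ri",
    "stiffness",
    "hrv",
    "balance",
    "balance_asym",
)
EXPLANATORY_COLUMNS = ("gender", "sport_type", "comp_level", "prev_injury")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroundTruthModel:
    """Generative model for a synthetic cohort.

    Discrete explanatory roots have explicit state probabilities;
    continuous measures are linear-Gaussian in their parents with an
    autoregressive carry-over between time points; negative life events
    are over-dispersed counts (gamma-Poisson) so a realistic share of
    zero scores occurs; injury per reporting interval is logistic in
    the standardised stiffness/life-event changes and the stiffness
    level at the interval start.
    """

    effect_scale: float = 1.0
    roots: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=lambda: {
            "gender": (("female", "male"), (0.34, 0.66)),
            "sport_type": (("individual", "team"), (0.40, 0.60)),
            "comp_level": (("club_university_county", "national_international"), (0.78, 0.22)),
            "prev_injury": (("no_injury", "injury"), (0.54, 0.46)),
        }
    )
    # Continuous-node parameters (means/effects/noise sd); AR carry-over rho.
    training_hours_base: float = 9.0
    training_hours_individual_effect: float = 3.5
    training_hours_sd: float = 3.0
    nle_mean_team: float = 3.2
    nle_mean_individual: float = 4.5
    nle_dispersion: float = 0.9        # gamma-Poisson shape; controls zero share
    stiffness_base: float = 2250.0
    stiffness_male_effect: float = 160.0
    stiffness_previnj_effect: float = 90.0
    stiffness_rho: float = 0.75
    stiffness_sd: float = 180.0
    hrv_base: float = 4.0              # ln(RMSSD) scale
    hrv_rho: float = 0.6
    hrv_sd: float = 0.55
    bis_base: float = 38.0
    bis_nle_effect: float = 0.35
    bis_rho: float = 0.7
    bis_sd: float = 6.0
    fffs_base: float = 17.0
    fffs_bis_slope: float = 0.25
    fffs_sd: float = 2.8
    ri_base: float = 10.0
    ri_sd: float = 2.2
    balance_base: float = 16.0
    balance_national_effect: float = -3.5
    balance_sd: float = 5.0
    injury_base_rate: float = 0.24
    injury_beta_dstiffness: float = 0.9
    injury_beta_dnle: float = 0.6
    injury_beta_stiffness_level: float = 0.8

    def __post_init__(self):
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if not 0 < self.injury_base_rate < 1:
            raise ValueError("injury base rate must lie in (0, 1)")
        for name, (states, probs) in self.roots.items():
            if len(states) != len(probs):
                raise ValueError(f"root {name!r}: states and probabilities differ in length")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"root {name!r}: probabilities do not sum to 1")
        self.graph().topological_order()  # raises on a cycle

    # -- structure -----------------------------------------------------

    def graph(self) -> Dag:
        """The generative dependency structure (per-time-point nodes)."""
        dag = Dag()
        for r in self.roots:
            dag.add_node(r)
        dag.add_node("training_hours")
        dag.add_arc("sport_type", "training_hours")
        prev = {}
        for t in (1, 2, 3):
            for base in ("nle", "bis", "fffs", "ri", "stiffness", "hrv", "balance"):
                dag.add_node(f"{base}_{t}")
            dag.add_arc("sport_type", f"nle_{t}")
            dag.add_arc(f"nle_{t}", f"bis_{t}")
            dag.add_arc(f"bis_{t}", f"fffs_{t}")
            dag.add_arc("gender", f"stiffness_{t}")
            dag.add_arc("prev_injury", f"stiffness_{t}")
            dag.add_arc("comp_level", f"balance_{t}")
            if prev:
                for base in ("bis", "stiffness", "hrv"):
                    dag.add_arc(f"{base}_{t-1}", f"{base}_{t}")
        for t in (2, 3, 4):
            dag.add_node(f"injured_{t}")
            src = min(t, 3)
            dag.add_arc(f"stiffness_{src}", f"injured_{t}")
            dag.add_arc(f"stiffness_{src - 1}", f"injured_{t}")
            dag.add_arc(f"nle_{src}", f"injured_{t}")
            dag.add_arc(f"nle_{src - 1}", f"injured_{t}")
        return dag

    # -- local conditionals --------------------------------------------

    def nle_zero_fraction(self, sport_individual: bool = False) -> float:
        """P(NLE score = 0) under the gamma-Poisson count model."""
        m = self.nle_mean_individual if sport_individual else self.nle_mean_team
        r = self.nle_dispersion
        return (r / (r + m)) ** r

    def injury_probability(
        self,
        d_stiffness_z: float | np.ndarray,
        d_nle_z: float | np.ndarray,
        stiffness_level_z: float | np.ndarray = 0.0,
    ) -> float | np.ndarray:
        """P(injured) for standardised changes/levels of the parents."""
        eta = math.log(self.injury_base_rate / (1 - self.injury_base_rate))
        eta = eta + self.effect_scale * (
            self.injury_beta_dstiffness * np.asarray(d_stiffness_z)
            + self.injury_beta_dnle * np.asarray(d_nle_z)
            + self.injury_beta_stiffness_level * np.asarray(stiffness_level_z)
        )
        return _sigmoid(eta)


def default_ground_truth(effect_scale: float = 1.0) -> GroundTruthModel:
    """The documented default model; see :class:`GroundTruthModel`."""
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    return GroundTruthModel(effect_scale=effect_scale)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for one synthetic cohort."""

    n_recruited: int = 351
    n_t1_only: int = 94
    missing_rate_stiffness: float = 0.0477
    missing_rate_hrv: float = 0.1077
    seed: int = 0

    def __post_init__(self):
        if self.n_recruited < 0:
            raise ValueError("n_recruited must be >= 0")
        if not 0 <= self.n_t1_only <= self.n_recruited:
            raise ValueError("need 0 <= n_t1_only <= n_recruited")
        for r in (self.missing_rate_stiffness, self.missing_rate_hrv):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")


def _empty_cohort() -> pd.DataFrame:
    cols = ["participant", "time", *EXPLANATORY_COLUMNS, *MEASURE_COLUMNS, "injured"]
    return pd.DataFrame({c: pd.Series(dtype="float64" if c in MEASURE_COLUMNS else "object") for c in cols})


def sample_cohort(model: GroundTruthModel, spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: one row per participant x time point.

    Participants retained past T1 contribute rows at T1-T3 (measures)
    and T2-T4 (injury reports; the T4 row carries only the report).
    Dropouts contribute a single T1 row.  Identical ``(model, spec)``
    give identical tables.
    """
    n = spec.n_recruited
    if n == 0:
        return _empty_cohort()
    ss = np.random.SeedSequence(spec.seed)
    rngs = {name: np.random.default_rng(child) for name, child in zip(
        ("roots", "hours", "nle", "psych", "physio", "injury", "dropout"), ss.spawn(7)
    )}

    cols: dict[str, np.ndarray] = {}
    for name, (states, probs) in model.roots.items():
        codes = rngs["roots"].choice(len(states), size=n, p=np.asarray(probs))
        cols[name] = np.asarray(states, dtype=object)[codes]
    male = cols["gender"] == "male"
    individual = cols["sport_type"] == "individual"
    national = cols["comp_level"] == "national_international"
    previnj = cols["prev_injury"] == "injury"

    hours = (
        model.training_hours_base
        + model.training_hours_individual_effect * individual
        + model.training_hours_sd * rngs["hours"].standard_normal(n)
    )
    hours = np.clip(hours, 1.0, None)

    # Per-time-point continuous measures with AR carry-over.
    nle = np.empty((3, n))
    ple = np.empty((3, n))
    bis = np.empty((3, n))
    fffs = np.empty((3, n))
    ri = np.empty((3, n))
    stiff = np.empty((3, n))
    hrv = np.empty((3, n))
    bal = np.empty((3, n))
    nle_mean = np.where(individual, model.nle_mean_individual, model.nle_mean_team)
    r = model.nle_dispersion
    for t in range(3):
        lam = rngs["nle"].gamma(shape=r, scale=nle_mean / r, size=n)
        nle[t] = rngs["nle"].poisson(lam)
        ple[t] = rngs["nle"].poisson(4.0, size=n)

        nle_z = (nle[t] - nle_mean) / np.sqrt(nle_mean * (1 + nle_mean / r))
        bis_mean = model.bis_base + model.bis_nle_effect * nle_z * 6.0
        if t == 0:
            bis[t] = bis_mean + model.bis_sd * rngs["psych"].standard_normal(n)
        else:
            bis[t] = (
                bis_mean
                + model.bis_rho * (bis[t - 1] - model.bis_base)
                + model.bis_sd * math.sqrt(1 - model.bis_rho**2) * rngs["psych"].standard_normal(n)
            )
        fffs[t] = (
            model.fffs_base
            + model.fffs_bis_slope * (bis[t] - model.bis_base)
            + model.fffs_sd * rngs["psych"].standard_normal(n)
        )
        ri[t] = model.ri_base + model.ri_sd * rngs["psych"].standard_normal(n)

        stiff_mean = (
            model.stiffness_base
            + model.stiffness_male_effect * male
            + model.stiffness_previnj_effect * previnj
        )
        if t == 0:
            stiff[t] = stiff_mean + model.stiffness_sd * rngs["physio"].standard_normal(n)
        else:
            stiff[t] = (
                stiff_mean
                + model.stiffness_rho * (stiff[t - 1] - stiff_mean)
                + model.stiffness_sd * math.sqrt(1 - model.stiffness_rho**2) * rngs["physio"].standard_normal(n)
            )
        if t == 0:
            hrv[t] = model.hrv_base + model.hrv_sd * rngs["physio"].standard_normal(n)
        else:
            hrv[t] = (
                model.hrv_base
                + model.hrv_rho * (hrv[t - 1] - model.hrv_base)
                + model.hrv_sd * math.sqrt(1 - model.hrv_rho**2) * rngs["physio"].standard_normal(n)
            )
        bal[t] = np.clip(
            model.balance_base
            + model.balance_national_effect * national
            + model.balance_sd * rngs["physio"].standard_normal(n),
            0.0,
            None,
        )

    # Injury per reporting interval.  Changes are standardised by the
    # model's own marginal change scales so probabilities are
    # well-defined per participant.
    d_stiff_sd = model.stiffness_sd * math.sqrt(2 * (1 - model.stiffness_rho))
    nle_var = nle_mean * (1 + nle_mean / r)
    d_nle_sd = np.sqrt(2 * nle_var)
    level_sd = model.stiffness_sd
    stiff_expected = (
        model.stiffness_base
        + model.stiffness_male_effect * male
        + model.stiffness_previnj_effect * previnj
    )
    injured = {}
    for report_t, (t0, t1) in zip((2, 3, 4), ((0, 1), (1, 2), (1, 2))):
        dz_stiff = (stiff[t1] - stiff[t0]) / d_stiff_sd
        dz_nle = (nle[t1] - nle[t0]) / d_nle_sd
        lz = (stiff[t0] - stiff_expected) / level_sd
        p = model.injury_probability(dz_stiff, dz_nle, lz)
        injured[report_t] = rngs["injury"].random(n) < p

    dropouts = rngs["dropout"].choice(n, size=spec.n_t1_only, replace=False)
    is_dropout = np.zeros(n, dtype=bool)
    is_dropout[dropouts] = True

    records = []
    width = max(3, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        base = {c: cols[c][i] for c in EXPLANATORY_COLUMNS}
        times = (0,) if is_dropout[i] else (0, 1, 2)
        for t in times:
            rec = {"participant": pid, "time": TIME_POINTS[t], **base}
            rec.update(
                training_hours=hours[i],
                nle=float(nle[t, i]),
                ple=float(ple[t, i]),
                tle=float(nle[t, i] + ple[t, i]),
                bis=bis[t, i],
                fffs=fffs[t, i],
                ri=ri[t, i],
                stiffness=stiff[t, i],
                hrv=hrv[t, i],
                balance=bal[t, i],
                balance_asym=0.0,
            )
            rec["injured"] = (
                ("injured" if injured[t + 1][i] else "healthy") if (t >= 1 and not is_dropout[i]) else None
            )
            records.append(rec)
        if not is_dropout[i]:
            rec = {"participant": pid, "time": "T4", **base}
            rec.update({c: np.nan for c in MEASURE_COLUMNS})
            rec["injured"] = "injured" if injured[4][i] else "healthy"
            records.append(rec)
    frame = pd.DataFrame.from_records(records)
    # T2/T3 injury columns double as interval reports: the value stored
    # on the T2 row is the report covering T1 -> T2, and so on.
    return frame


def inject_missingness(cohort: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Set stiffness/HRV measurements missing completely at random.

    Each non-missing measurement is dropped independently with the
    spec's rate; boolean ``*_missing`` flag columns record which.  All
    other fields are untouched.  The input must not already contain
    missing stiffness/HRV measurements (on measurement rows).
    """
    out = cohort.copy()
    measure_rows = out["time"].isin(TIME_POINTS)
    for col in ("stiffness", "hrv"):
        if out.loc[measure_rows, col].isna().any():
            raise ValueError(f"cohort already has missing {col} measurements")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA11C)))
    for col, rate in (("stiffness", spec.missing_rate_stiffness), ("hrv", spec.missing_rate_hrv)):
        flag = np.zeros(len(out), dtype=bool)
        idx = np.flatnonzero(measure_rows.to_numpy())
        flag[idx] = rng.random(idx.size) < rate
        out[f"{col}_missing"] = flag
        out.loc[flag, col] = np.nan
    return out


def generate_ibi_series(
    mean_ibi: float,
    target_rmssd: float,
    duration: float,
    seed: int | None = None,
    artifact_rate: float = 0.0,
) -> IbiSeries:
    """Construct an IBI recording with a known RMSSD.

    Beats alternate ``mean_ibi +/- target_rmssd/2`` so every successive
    difference has magnitude ``target_rmssd`` and the windowed RMSSD
    equals the target exactly.  ``artifact_rate`` optionally replaces a
    random fraction of beats with doubled intervals (ectopic-like
    spikes) to exercise the adaptive filter.
    """
    if mean_ibi <= 0:
        raise ValueError("mean_ibi must be > 0")
    if target_rmssd < 0:
        raise ValueError("target_rmssd must be >= 0")
    if target_rmssd >= mean_ibi:
        raise ValueError("target_rmssd must be smaller than mean_ibi")
    if duration < 600:
        raise ValueError("duration must be >= 600 s to leave a 5-min analysis window")
    if not 0.0 <= artifact_rate < 1.0:
        raise ValueError("artifact_rate must lie in [0, 1)")
    n = int(math.ceil(duration * 1000.0 / mean_ibi)) + 1
    offsets = np.where(np.arange(n) % 2 == 0, +target_rmssd / 2.0, -target_rmssd / 2.0)
    intervals = np.full(n, float(mean_ibi)) + offsets
    if artifact_rate > 0:
        rng = np.random.default_rng(seed)
        k = int(round(artifact_rate * n))
        pos = rng.choice(n, size=k, replace=False)
        intervals[pos] *= 2.0
    return IbiSeries(intervals)
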
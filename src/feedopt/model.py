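"""Fitted milk protein-plus-fat production function for grazing dairy cows.

The response model is a mixed-model meta-analysis fit across Australian
grazing experiments: daily milk protein plus fat yield (kg/cow·day) as a
bivariate quadratic in concentrate DMI and pooled pasture + forage DMI,
adjusted for centred animal and pasture covariates (pre-experimental yield,
weeks lactating, season, liveweight group, pasture digestibility) and a
season × concentrate interaction.  Only the fixed effects are used for
prediction.

Two prediction modes are exposed:

``predict_absolute_yield``
    evaluates the full fixed-effect equation — covariates and all.

``predict_marginal_yield``
    anchors the prediction at the herd's *current* measured yield and adds
    only the change in the intake-dependent part of the model between the
    current and the candidate intakes.  All purely covariate terms cancel
    exactly in the difference, so this mode needs no digestibility input
    and is robust to covariates that were only ever observed on the
    meta-analysis scale.  It is the mode used for the economic analysis.

``reduce_to_quadratic`` rewrites the model, for one fixed cow state, as the
plain two-input quadratic  Y = a0 + a1·X1 + a2·X2 + a11·X1² + a22·X2² +
a12·X1·X2  (X1 = concentrate DMI, X2 = pasture + forage DMI) on which the
production-economics calculus in :mod:`feedopt.economics` operates.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

__all__ = [
    "SEASONS",
    "ModelCoefficients",
    "CowState",
    "ReducedQuadratic",
    "CalibrationEnvelopeWarning",
    "dmd_from_me",
    "linear_predictor",
    "predict_absolute_yield",
    "predict_marginal_yield",
    "reduce_to_quadratic",
]

logger = logging.getLogger(__name__)

SEASONS = ("Spring", "Summer", "Autumn", "Winter")

#: kg liveweight separating the two liveweight groups; at or below maps to
#: the reference (zero-coefficient) group.
LIVEWEIGHT_BOUNDARY_KG = 500.0

#: DMD% = ME / ME_PER_DMD converts pasture metabolisable energy (MJ/kg DM)
#: to in vitro dry matter digestibility (%).  A simple linear convention
#: (16 kJ of ME per percentage point of DMD per kg DM); supply DMD directly
#: to bypass it.
ME_PER_DMD = 0.16

# Calibration envelope of the underlying experimental database: predictions
# outside it are extrapolation and are flagged with a warning.
WEEKS_ENVELOPE = (3.0, 39.0)        # ~18-270 days in milk
LIVEWEIGHT_ENVELOPE = (400.0, 600.0)


class CalibrationEnvelopeWarning(UserWarning):
    """Requested prediction lies outside the fitted data envelope."""


def dmd_from_me(me: float) -> float:
    """Convert pasture metabolisable energy to dry matter digestibility.

    Parameters
    ----------
    me : float
        Metabolisable energy of pasture consumed, MJ/kg DM.  Must lie in
        [4, 14], the plausible range for temperate pastures and forages.

    Returns
    -------
    float
        In vitro dry matter digestibility, % of DM, computed as
        ``me / 0.16``.  Digestibility only enters absolute predictions;
        marginal (baseline-anchored) predictions are unaffected.
    """
    if not 4.0 <= me <= 14.0:
        raise ValueError(
            f"pasture ME {me} MJ/kg DM outside the plausible range [4, 14]"
        )
    return me / ME_PER_DMD


@dataclass(frozen=True)
class ModelCoefficients:
    """Fixed-effect coefficients and covariate means of the fitted model.

    Units: the intercept and season/liveweight offsets are kg/cow·day;
    slopes are kg per unit of their covariate (kg per kg DM for intakes,
    kg per (kg DM)² for the quadratic and cross terms, kg per week, kg per
    % digestibility).  ``covariate_means`` holds the centring constants of
    the meta-analysis (each covariate enters as value − mean).

    The per-experiment random intercept/slope and the residual term of the
    meta-analysis model are *not* part of this object — prediction uses
    fixed effects only.  The random structure lives in
    :class:`feedopt.metafit.RandomStructure`.
    """

    intercept: float
    pre_experimental: float
    weeks: float
    pf_linear: float
    pf_quadratic: float
    conc_linear: float
    conc_quadratic: float
    cross: float
    season_main: dict[str, float]
    season_conc_interaction: dict[str, float]
    lwt_group: dict[str, float]
    dmd: float
    covariate_means: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pf_quadratic >= 0 or self.conc_quadratic >= 0:
            raise ValueError(
                "quadratic intake coefficients must be negative "
                "(diminishing returns)"
            )
        for season in SEASONS:
            if season not in self.season_main:
                raise ValueError(f"season_main missing season {season!r}")
            if season not in self.season_conc_interaction:
                raise ValueError(
                    f"season_conc_interaction missing season {season!r}"
                )
        if self.season_main["Spring"] != 0.0:
            raise ValueError("Spring is the reference season: main effect 0")
        if self.season_conc_interaction["Spring"] != 0.0:
            raise ValueError(
                "Spring is the reference season: conc interaction 0"
            )
        if self.lwt_group.get("le_500") != 0.0:
            raise ValueError("liveweight group <=500 kg is the reference: 0")

    @classmethod
    def from_tables(
        cls,
        coefficients: pd.DataFrame,
        means: pd.DataFrame,
    ) -> "ModelCoefficients":
        """Build from the packaged two-table schema.

        ``coefficients`` needs columns ``term, coefficient, se``;
        ``means`` needs ``covariate, mean``.  Term and covariate names
        follow the packaged CSV files.
        """
        c = coefficients.set_index("term")["coefficient"].astype(float)
        se = (
            coefficients.dropna(subset=["se"])
            .set_index("term")["se"]
            .astype(float)
            .to_dict()
        )
        m = means.set_index("covariate")["mean"].astype(float)
        return cls(
            intercept=c["constant"],
            pre_experimental=c["pre_experimental"],
            weeks=c["weeks_lactating"],
            pf_linear=c["dmi_pasture_forage"],
            pf_quadratic=c["dmi_pasture_forage_sq"],
            conc_linear=c["dmi_concentrate"],
            conc_quadratic=c["dmi_concentrate_sq"],
            cross=c["dmi_pasture_forage_x_concentrate"],
            season_main={
                "Spring": c["season_spring"],
                "Summer": c["season_summer"],
                "Autumn": c["season_autumn"],
                "Winter": c["season_winter"],
            },
            season_conc_interaction={
                "Spring": c["conc_x_season_spring"],
                "Summer": c["conc_x_season_summer"],
                "Autumn": c["conc_x_season_autumn"],
                "Winter": c["conc_x_season_winter"],
            },
            lwt_group={
                "le_500": c["lwt_group_le_500"],
                "gt_500": c["lwt_group_gt_500"],
            },
            dmd=c["pasture_dmd"],
            covariate_means={
                "pre_experimental": m["pre_experimental"],
                "weeks_lactating": m["weeks_lactating"],
                "pf": m["dmi_pasture_forage"],
                "pf_sq": m["dmi_pasture_forage_sq"],
                "conc": m["dmi_concentrate"],
                "conc_sq": m["dmi_concentrate_sq"],
                "cross": m["dmi_pasture_forage_x_concentrate"],
                "dmd": m["pasture_dmd"],
            },
            standard_errors=se,
        )

    @classmethod
    def default(cls) -> "ModelCoefficients":
        """The packaged published coefficient set.

        Winter carries the pooled winter/spring season main effect (0) and,
        because no winter × concentrate interaction was published, defaults
        that interaction to autumn's value (0.030 kg per kg DM) — the choice
        consistent with the published winter optimisation results.  The
        substitution is logged; override by loading an edited table.
        """
        with resources.files("feedopt.data").joinpath(
            "model_coefficients.csv"
        ).open() as fh:
            coef = pd.read_csv(fh)
        with resources.files("feedopt.data").joinpath(
            "covariate_means.csv"
        ).open() as fh:
            means = pd.read_csv(fh)
        obj = cls.from_tables(coef, means)
        logger.info(
            "winter season x concentrate interaction unpublished; "
            "defaulting to autumn's value %.3f",
            obj.season_conc_interaction["Winter"],
        )
        return obj

    @classmethod
    def from_csv(cls, coefficients_path, means_path) -> "ModelCoefficients":
        """Load an alternative coefficient set from two CSV files."""
        return cls.from_tables(
            pd.read_csv(coefficients_path), pd.read_csv(means_path)
        )

    def checksum(self) -> str:
        """Stable sha256 over the coefficient values (for run manifests)."""
        parts = [
            f"{k}={v!r}"
            for k, v in sorted(vars(self).items())
            if k != "standard_errors"
        ]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CowState:
    """Scenario covariates describing one herd at the decision point.

    ``current_yield`` is the herd's measured milk protein plus fat yield
    (kg/cow·day) at the current intakes; it doubles as the model's
    pre-experimental covariate and as the anchor for marginal predictions.
    Exactly one of ``pasture_dmd`` (% DM digestibility) or ``pasture_me``
    (MJ/kg DM) is needed for absolute predictions; marginal predictions
    need neither.
    """

    season: str
    current_yield: float
    weeks_lactating: float
    liveweight: float | None = None
    lwt_group: str | None = None        # "le_500" | "gt_500"; overrides liveweight
    pasture_dmd: float | None = None
    pasture_me: float | None = None
    current_conc_dmi: float = 0.0
    current_pasture_dmi: float = 0.0
    current_forage_dmi: float = 0.0

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(
                f"unknown season {self.season!r}; expected one of {SEASONS}"
            )
        if self.current_yield <= 0:
            raise ValueError("current_yield must be positive")
        for name in (
            "current_conc_dmi",
            "current_pasture_dmi",
            "current_forage_dmi",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lwt_group is not None and self.lwt_group not in (
            "le_500",
            "gt_500",
        ):
            raise ValueError("lwt_group must be 'le_500' or 'gt_500'")
        if self.lwt_group is None and self.liveweight is None:
            raise ValueError("supply liveweight or an explicit lwt_group")
        lo, hi = WEEKS_ENVELOPE
        if not lo <= self.weeks_lactating <= hi:
            warnings.warn(
                f"weeks_lactating={self.weeks_lactating} outside the "
                f"calibration envelope [{lo}, {hi}] (~18-270 days in milk); "
                "responses there are largely untested",
                CalibrationEnvelopeWarning,
                stacklevel=2,
            )
        if self.liveweight is not None:
            lo, hi = LIVEWEIGHT_ENVELOPE
            if not lo <= self.liveweight <= hi:
                warnings.warn(
                    f"liveweight={self.liveweight} kg outside the "
                    f"calibration envelope [{lo}, {hi}] kg",
                    CalibrationEnvelopeWarning,
                    stacklevel=2,
                )

    @property
    def current_pf_dmi(self) -> float:
        """Pooled current pasture + forage intake, kg DM/cow·day."""
        return self.current_pasture_dmi + self.current_forage_dmi

    def resolve_lwt_group(self) -> str:
        if self.lwt_group is not None:
            return self.lwt_group
        return "le_500" if self.liveweight <= LIVEWEIGHT_BOUNDARY_KG else "gt_500"

    def resolve_dmd(self) -> float:
        """Digestibility (%), converting from ME when DMD is not given."""
        if self.pasture_dmd is not None:
            return self.pasture_dmd
        if self.pasture_me is not None:
            return dmd_from_me(self.pasture_me)
        raise ValueError(
            "absolute prediction needs pasture digestibility: supply "
            "pasture_dmd (%) or pasture_me (MJ/kg DM)"
        )

    def with_intakes(
        self, conc: float, pasture: float, forage: float = 0.0
    ) -> "CowState":
        return replace(
            self,
            current_conc_dmi=conc,
            current_pasture_dmi=pasture,
            current_forage_dmi=forage,
        )


@dataclass(frozen=True)
class ReducedQuadratic:
    """Two-input quadratic production function for one fixed cow state.

    Y = a0 + a1·X1 + a2·X2 + a11·X1² + a22·X2² + a12·X1·X2, with
    X1 = concentrate DMI and X2 = pasture + forage DMI (kg DM/cow·day) and
    Y in kg milk protein plus fat/cow·day.  ``a0`` is anchored so the
    quadratic reproduces the state's current yield at its current intakes.
    """

    a0: float
    a1: float
    a2: float
    a11: float
    a22: float
    a12: float

    def __post_init__(self) -> None:
        if self.a11 >= 0 or self.a22 >= 0:
            raise ValueError("a11 and a22 must be negative (concavity)")

    def __call__(self, x1, x2):
        """Evaluate the yield surface; accepts scalars or arrays."""
        return (
            self.a0
            + self.a1 * x1
            + self.a2 * x2
            + self.a11 * x1 * x1
            + self.a22 * x2 * x2
            + self.a12 * x1 * x2
        )

    def is_concave(self) -> bool:
        """Negative-definiteness of the Hessian [[2a11, a12], [a12, 2a22]]."""
        return self.a11 < 0 and 4 * self.a11 * self.a22 - self.a12**2 > 0


def linear_predictor(
    coeffs: ModelCoefficients,
    *,
    season: str = "Spring",
    lwt_group: str = "le_500",
    pre_experimental: float | None = None,
    weeks: float | None = None,
    pf: float | None = None,
    pf_sq: float | None = None,
    conc: float | None = None,
    conc_sq: float | None = None,
    cross: float | None = None,
    dmd: float | None = None,
) -> float:
    """Fixed-effect linear predictor on the meta-analysis covariate scale.

    Each covariate enters centred at its own mean; the squared and
    cross-product intake covariates are *separate* regressors here, each
    with its own centring mean, exactly as the model was estimated.  Any
    covariate left as ``None`` sits at its mean and contributes nothing —
    with everything at the means the predictor equals the intercept.
    The season × concentrate interaction multiplies the centred
    concentrate DMI.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    m = coeffs.covariate_means
    defaults = {
        "pre_experimental": m["pre_experimental"],
        "weeks": m["weeks_lactating"],
        "pf": m["pf"],
        "pf_sq": m["pf_sq"],
        "conc": m["conc"],
        "conc_sq": m["conc_sq"],
        "cross": m["cross"],
        "dmd": m["dmd"],
    }
    v = {
        k: (defaults[k] if val is None else val)
        for k, val in dict(
            pre_experimental=pre_experimental,
            weeks=weeks,
            pf=pf,
            pf_sq=pf_sq,
            conc=conc,
            conc_sq=conc_sq,
            cross=cross,
            dmd=dmd,
        ).items()
    }
    conc_centred = v["conc"] - m["conc"]
    return (
        coeffs.intercept
        + coeffs.pre_experimental * (v["pre_experimental"] - m["pre_experimental"])
        + coeffs.weeks * (v["weeks"] - m["weeks_lactating"])
        + coeffs.season_main[season]
        + coeffs.pf_linear * (v["pf"] - m["pf"])
        + coeffs.conc_linear * conc_centred
        + coeffs.pf_quadratic * (v["pf_sq"] - m["pf_sq"])
        + coeffs.conc_quadratic * (v["conc_sq"] - m["conc_sq"])
        + coeffs.cross * (v["cross"] - m["cross"])
        + coeffs.season_conc_interaction[season] * conc_centred
        + coeffs.lwt_group[lwt_group]
        + coeffs.dmd * (v["dmd"] - m["dmd"])
    )


def _intake_terms(
    coeffs: ModelCoefficients, season: str, conc: float, pf: float
) -> float:
    """Intake-dependent part of the model, uncentred.

    Linear, quadratic, cross and season × concentrate terms; centring
    shifts each of these by a constant that cancels in any difference.
    """
    a1 = coeffs.conc_linear + coeffs.season_conc_interaction[season]
    return (
        a1 * conc
        + coeffs.pf_linear * pf
        + coeffs.conc_quadratic * conc * conc
        + coeffs.pf_quadratic * pf * pf
        + coeffs.cross * conc * pf
    )


def predict_absolute_yield(
    coeffs: ModelCoefficients,
    state: CowState,
    conc_dmi: float,
    pf_dmi: float,
) -> float:
    """Evaluate the full fixed-effect equation at the given intakes.

    All covariates enter centred (value minus its meta-analysis mean), so
    with every covariate at its mean the prediction equals the intercept.
    Requires a resolvable pasture digestibility.

    Parameters
    ----------
    conc_dmi, pf_dmi : float
        Candidate concentrate and pooled pasture + forage intakes,
        kg DM/cow·day.

    Returns
    -------
    float
        Predicted milk protein plus fat yield, kg/cow·day.
    """
    if conc_dmi < 0 or pf_dmi < 0:
        raise ValueError("intakes must be non-negative")
    return linear_predictor(
        coeffs,
        season=state.season,
        lwt_group=state.resolve_lwt_group(),
        pre_experimental=state.current_yield,
        weeks=state.weeks_lactating,
        pf=pf_dmi,
        pf_sq=pf_dmi**2,
        conc=conc_dmi,
        conc_sq=conc_dmi**2,
        cross=conc_dmi * pf_dmi,
        dmd=state.resolve_dmd(),
    )


def predict_marginal_yield(
    coeffs: ModelCoefficients,
    state: CowState,
    conc_dmi: float,
    pf_dmi: float,
) -> float:
    """Baseline-anchored yield prediction at candidate intakes.

    Returns ``current_yield + [Q(candidate) − Q(current)]`` where Q is the
    intake-dependent part of the model (linear, quadratic, cross and
    season × concentrate terms).  Every purely covariate term — intercept,
    pre-experimental yield, weeks, season main effect, liveweight group,
    digestibility — cancels exactly, so the marginal prediction responds
    only to the intake change.  This mode underlies the economic analysis.
    """
    if conc_dmi < 0 or pf_dmi < 0:
        raise ValueError("intakes must be non-negative")
    q_new = _intake_terms(coeffs, state.season, conc_dmi, pf_dmi)
    q_cur = _intake_terms(
        coeffs, state.season, state.current_conc_dmi, state.current_pf_dmi
    )
    return state.current_yield + q_new - q_cur


def reduce_to_quadratic(
    coeffs: ModelCoefficients, state: CowState
) -> ReducedQuadratic:
    """Collapse the model, for one cow state, to the two-input quadratic.

    The slopes come straight off the fitted coefficients
    (a1 = conc linear + season interaction, a2 = pasture+forage linear,
    a11/a22 the quadratics, a12 the cross term); the constant ``a0`` is
    chosen so the quadratic passes through (current intakes, current
    yield), making it the marginal-prediction surface in closed form.
    """
    a1 = coeffs.conc_linear + coeffs.season_conc_interaction[state.season]
    a2 = coeffs.pf_linear
    a11 = coeffs.conc_quadratic
    a22 = coeffs.pf_quadratic
    a12 = coeffs.cross
    c, p = state.current_conc_dmi, state.current_pf_dmi
    a0 = state.current_yield - (
        a1 * c + a2 * p + a11 * c * c + a22 * p * p + a12 * c * p
    )
    return ReducedQuadratic(a0=a0, a1=a1, a2=a2, a11=a11, a22=a22, a12=a12)
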
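"""Composition-driven freezing-point theory.

An ice-cream mix depresses its freezing point through the colligative
solutes it carries: sugars and polyols, the salt fraction of milk solids,
and added NaCl.  The standard industrial treatment converts every sugar to
the mass of sucrose with the same mole count (*sucrose equivalents*, SE),
looks the depression up on a pure-sucrose table, and adds separate linear
terms for milk solids-non-fat (MSNF) and NaCl.

Solute-solvent interaction strength is characterised with the Weast linear
plot: the water/solute ratio Mw/Ms regressed on the reciprocal magnitude of
the measured freezing point.

Per-100-g bookkeeping conventions used throughout:

* ``Mw`` -- water, g per 100 g of mixture;
* sugar concentrations and SE -- g per 100 g of *water*;
* MSNF -- protein + ash + other non-lactose milk solids (lactose is counted
  as a colligative sugar with the molecular weight of sucrose).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq

from .errors import RangeError, ValidationError

#: cryoscopic constant of water, degC kg/mol
KF_WATER = 1.86
#: ions per formula unit of fully dissociated NaCl
NACL_IONS = 2
MW_NACL = 58.44
MW_SUCROSE = 342.30
#: default MSNF freezing-point coefficient, degC per (g MSNF / g water)
MSNF_FPD_COEFF = 2.37

#: composition fields treated as colligative sugars (converted to SE)
SUGAR_SPECIES = ("sucrose", "dextrose", "fructose", "sorbitol", "lactose", "maltodextrin", "inulin")
#: remaining recognised composition fields, g per 100 g of ingredient
OTHER_SPECIES = ("water", "fat", "protein", "ash", "nacl", "other_solids")
ALL_SPECIES = SUGAR_SPECIES + OTHER_SPECIES


def _data_path(name: str):
    return resources.files("icekin.data").joinpath(name)


def load_mw_table(path=None) -> dict[str, float]:
    """Molecular weights (g/mol) of the colligative species, from packaged CSV."""
    src = path if path is not None else _data_path("molecular_weights.csv")
    table = {}
    with open(src) as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "species":
                continue
            table[row[0]] = float(row[1])
    return table


def load_milk_composition(path=None) -> dict[str, float]:
    """Default whole-milk composition, g per 100 g."""
    src = path if path is not None else _data_path("whole_milk.yaml")
    with open(src) as fh:
        return {k: float(v) for k, v in yaml.safe_load(fh).items()}


class SucroseFpdTable:
    """Packaged sucrose freezing-point-depression table with a polynomial fit.

    The table maps g sucrose / 100 g water to the depression in degC.  A
    zero-intercept polynomial (default cubic) is fitted once at load time, so
    FPD(0) = 0 exactly; queries outside the tabulated domain raise
    :class:`RangeError`.
    """

    def __init__(self, path=None, order: int = 3):
        src = path if path is not None else _data_path("sucrose_fpd_v1.csv")
        conc, dep = [], []
        with open(src) as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0].startswith("se_"):
                    continue
                conc.append(float(row[0]))
                dep.append(float(row[1]))
        self.concentration = np.asarray(conc)
        self.depression = np.asarray(dep)
        self.order = order
        self.version = getattr(src, "name", str(src))
        # zero-intercept fit: basis x, x^2, ..., x^order
        powers = np.arange(1, order + 1)
        A = self.concentration[:, None] ** powers[None, :]
        self.coeffs, *_ = np.linalg.lstsq(A, self.depression, rcond=None)
        self._powers = powers

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.concentration[0]), float(self.concentration[-1])

    def fpd(self, se) -> float | np.ndarray:
        """Freezing-point depression (degC, positive) at SE g/100 g water."""
        se_arr = np.asarray(se, dtype=float)
        lo, hi = self.domain
        if np.any(se_arr < lo - 1e-9) or np.any(se_arr > hi + 1e-9):
            raise RangeError(
                f"sucrose equivalents {se_arr[(se_arr < lo) | (se_arr > hi)]} outside "
                f"table domain [{lo}, {hi}] g/100 g water"
            )
        out = (se_arr[..., None] ** self._powers).dot(self.coeffs)
        return float(out) if np.isscalar(se) or se_arr.ndim == 0 else out

    def inverse(self, fpd_value: float) -> float:
        """SE (g/100 g water) whose tabulated depression equals ``fpd_value``."""
        lo, hi = self.domain
        if fpd_value < 0 or fpd_value > self.fpd(hi):
            raise RangeError(f"FPD {fpd_value} degC outside invertible range")
        if fpd_value == 0:
            return 0.0
        return brentq(lambda s: self.fpd(s) - fpd_value, lo, hi, xtol=1e-10)


_default_table: SucroseFpdTable | None = None


def default_sucrose_table() -> SucroseFpdTable:
    global _default_table
    if _default_table is None:
        _default_table = SucroseFpdTable()
    return _default_table


@dataclass(frozen=True)
class Ingredient:
    """One recipe line: mass in g and composition in g per 100 g of ingredient."""

    name: str
    mass: float
    composition: dict[str, float]

    def __post_init__(self):
        if self.mass <= 0:
            raise ValidationError(f"ingredient {self.name!r}: mass must be > 0")
        unknown = set(self.composition) - set(ALL_SPECIES)
        if unknown:
            raise ValidationError(f"ingredient {self.name!r}: unknown species {sorted(unknown)}")
        total = sum(self.composition.values())
        if total > 100.0 + 1e-6:
            raise ValidationError(
                f"ingredient {self.name!r}: composition sums to {total} g/100 g > 100"
            )
        if any(v < 0 for v in self.composition.values()):
            raise ValidationError(f"ingredient {self.name!r}: negative composition entry")


@dataclass(frozen=True)
class Formulation:
    """A recipe: list of ingredients with per-100-g compositions."""

    ingredients: tuple[Ingredient, ...]
    name: str = ""

    def __post_init__(self):
        if not self.ingredients:
            raise ValidationError("formulation needs at least one ingredient")
        object.__setattr__(self, "ingredients", tuple(self.ingredients))

    @property
    def total_mass(self) -> float:
        return sum(i.mass for i in self.ingredients)

    @classmethod
    def from_dict(cls, spec: dict) -> "Formulation":
        milk = load_milk_composition()
        ingredients = []
        for item in spec.get("ingredients", []):
            comp = item.get("composition")
            if comp is None:
                key = item["name"].strip().lower().replace(" ", "_")
                if key in ("whole_milk", "milk"):
                    comp = milk
                elif key == "water":
                    comp = {"water": 100.0}
                elif key in SUGAR_SPECIES:
                    comp = {key: 100.0}
                elif key == "nacl":
                    comp = {"nacl": 100.0}
                else:
                    raise ValidationError(
                        f"ingredient {item['name']!r} needs an explicit composition"
                    )
            ingredients.append(Ingredient(item["name"], float(item["mass"]), dict(comp)))
        return cls(tuple(ingredients), name=spec.get("name", ""))

    @classmethod
    def from_yaml(cls, path) -> "Formulation":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ColligativeProfile:
    """Per-100-g mass balance of a formulation, on the colligative bookkeeping.

    sugars_per_100g_water maps each sugar species to g per 100 g water;
    ``se`` (sucrose equivalents, g/100 g water) and ``mw_over_ms`` are filled
    in by :func:`sucrose_equivalents` / :func:`build_profile`.
    """

    mw: float  # water, g per 100 g mixture
    sugars_per_100g_water: dict[str, float]
    msnf_per_100g_water: float
    nacl_per_100g_water: float
    fat_per_100g: float = 0.0
    msnf_per_100g: float = 0.0
    nacl_per_100g: float = 0.0
    se: float | None = None
    mw_over_ms: float | None = None


def mass_balance(f: Formulation) -> ColligativeProfile:
    """Aggregate a recipe into per-100-g totals on the colligative conventions."""
    total = f.total_mass
    if total <= 0:
        raise ValidationError("zero total mass")
    grams = {sp: 0.0 for sp in ALL_SPECIES}
    for ing in f.ingredients:
        for sp, per100 in ing.composition.items():
            grams[sp] += ing.mass * per100 / 100.0
    water = grams["water"]
    if water <= 0:
        raise ValidationError("formulation contains no water")
    per100 = {sp: 100.0 * g / total for sp, g in grams.items()}
    per100w = {sp: 100.0 * g / water for sp, g in grams.items()}
    msnf_w = per100w["protein"] + per100w["ash"] + per100w["other_solids"]
    return ColligativeProfile(
        mw=per100["water"],
        sugars_per_100g_water={sp: per100w[sp] for sp in SUGAR_SPECIES if per100w[sp] > 0},
        msnf_per_100g_water=msnf_w,
        nacl_per_100g_water=per100w["nacl"],
        fat_per_100g=per100["fat"],
        msnf_per_100g=per100["protein"] + per100["ash"] + per100["other_solids"],
        nacl_per_100g=per100["nacl"],
    )


def sucrose_equivalents(p: ColligativeProfile, mw_table: dict[str, float] | None = None) -> float:
    """Total sucrose equivalents, g per 100 g water.

    Each sugar is converted by the molecular-weight ratio
    SE_s = c_s x MW_sucrose / MW_s, so a mole of any sugar counts as a mole
    of sucrose.  Lactose from milk is included as a colligative sugar.
    """
    table = mw_table if mw_table is not None else load_mw_table()
    se = 0.0
    for sp, conc in p.sugars_per_100g_water.items():
        if sp not in table:
            raise ValidationError(f"no molecular weight for sugar species {sp!r}")
        se += conc * MW_SUCROSE / table[sp]
    return se


def build_profile(f: Formulation, mw_table: dict[str, float] | None = None) -> ColligativeProfile:
    """Mass balance plus SE and Mw/Ms in one call."""
    p = mass_balance(f)
    p.se = sucrose_equivalents(p, mw_table)
    p.mw_over_ms = p.mw / p.se if p.se > 0 else None
    return p


def fpd_contributions(
    p: ColligativeProfile,
    table: SucroseFpdTable | None = None,
    msnf_coeff: float = MSNF_FPD_COEFF,
) -> dict[str, float]:
    """Per-solute-class freezing-point-depression terms, degC (positive)."""
    tab = table if table is not None else default_sucrose_table()
    se = p.se if p.se is not None else sucrose_equivalents(p)
    molality_nacl = p.nacl_per_100g_water * 10.0 / MW_NACL  # mol per kg water
    return {
        "sugars": float(tab.fpd(se)) if se > 0 else 0.0,
        "msnf": msnf_coeff * p.msnf_per_100g_water / 100.0,
        "nacl": KF_WATER * NACL_IONS * molality_nacl,
    }


def theoretical_freezing_point(
    p: ColligativeProfile,
    table: SucroseFpdTable | None = None,
    msnf_coeff: float = MSNF_FPD_COEFF,
) -> float:
    """Theoretical freezing point FPt in degC (<= 0).

    FPt = -(FPD_sucrose(SE) + FPD_MSNF + FPD_NaCl): the sucrose-table term
    for all sugars via SE, a linear MSNF term, and the ideal colligative law
    for fully dissociated NaCl.
    """
    return -sum(fpd_contributions(p, table, msnf_coeff).values())


@dataclass(frozen=True)
class WeastFit:
    """OLS summary of the interaction linear plot y = Mw/Ms vs x = 1/|FP|."""

    slope: float
    intercept: float
    r_squared: float


def weast_fit(points: list[tuple[float, float]]) -> WeastFit:
    """Fit the Weast interaction linear plot.

    ``points`` are (FP degC, Mw/Ms) pairs with FP < 0; the regression is of
    Mw/Ms on 1/|FP|.  The intercept measures solute-solvent interaction
    strength, the slope the dependence of the freezing point on dilution.
    """
    if len(points) < 2:
        raise ValidationError("need at least two points for the Weast fit")
    fp = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.any(fp >= 0):
        raise ValidationError("all freezing points must be < 0 degC")
    x = 1.0 / np.abs(fp)
    res = stats.linregress(x, y)
    return WeastFit(float(res.slope), float(res.intercept), float(res.rvalue**2))
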
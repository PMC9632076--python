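"""Demographic scenarios for structured, serially sampled mitogenome data.

Four competing scenarios for a set of temporally stratified populations
("demes") of a single species are supported:

``constant``
    Constant female effective size through time.
``lgm``
    A transient bottleneck during the Last Glacial Maximum (LGM).
``eemian``
    A transient bottleneck during the Eemian interglacial.
``lgm_eemian``
    Both bottlenecks.

Each scenario shares the same population layout: demes carry a clade label,
a sampling age (years BP) and a female effective size N_ef; join events move
all lineages of one deme into another backwards in time, encoding the clade
most-recent-common-ancestor structure.  Bottlenecks multiply deme sizes by a
severity factor b in (0, 1] over a time window, with the onset drawn from a
log-uniform prior (LGM 30-20 kya, Eemian 130-115 kya by default) and the
severity from a uniform prior on [0.2, 0.6].
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

SCENARIOS = ("constant", "lgm", "eemian", "lgm_eemian")

#: climatic window lengths (years) used as default bottleneck durations
DEFAULT_DURATIONS = {"LGM": 8_600.0, "Eemian": 15_000.0}


@dataclass(frozen=True)
class Prior:
    """A univariate prior: ``log-uniform``, ``uniform`` or ``fixed``.

    For ``fixed`` only ``lower`` is used (the point mass).
    """

    kind: str
    lower: float
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("log-uniform", "uniform", "fixed"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "fixed":
            return
        if self.upper is None or not self.lower < self.upper:
            raise ValueError(
                f"{self.kind} prior requires lower < upper, got "
                f"[{self.lower}, {self.upper}]"
            )
        if self.kind == "log-uniform" and self.lower <= 0:
            raise ValueError("log-uniform prior requires lower > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.lower)
        if self.kind == "uniform":
            return float(rng.uniform(self.lower, self.upper))
        return float(np.exp(rng.uniform(np.log(self.lower), np.log(self.upper))))

    def mean(self) -> float:
        """Analytic mean; for the log-uniform this is (b-a)/ln(b/a)."""
        if self.kind == "fixed":
            return float(self.lower)
        if self.kind == "uniform":
            return (self.lower + self.upper) / 2.0
        return (self.upper - self.lower) / math.log(self.upper / self.lower)

    def contains(self, x: float) -> bool:
        if self.kind == "fixed":
            return math.isclose(x, self.lower)
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class DemeSpec:
    """One population: a clade sampled at one point in time."""

    deme_id: str
    clade_label: str
    sampling_time: float  # years BP
    n_samples: int
    size_females: float  # N_ef


@dataclass(frozen=True)
class JoinEvent:
    """Backward in time at ``time`` (years BP), all lineages of
    ``source_deme`` move into ``dest_deme``."""

    time: float
    source_deme: str
    dest_deme: str


@dataclass(frozen=True)
class BottleneckSpec:
    """A size reduction over a window: at a drawn onset (years BP, most
    recent edge of the window) the deme size is multiplied by a drawn
    severity b for ``duration`` years further back in time."""

    label: str  # "LGM" or "Eemian"
    timing_prior: Prior
    severity_prior: Prior
    duration: float


@dataclass(frozen=True)
class ClockConfig:
    """Calendar/mutation clock: g generations per year, per-site per-
    generation mutation rate mu, and sequence length L."""

    generations_per_year: float = 2.0
    mu_per_site_per_gen: float = 1.035e-7
    seq_length: int = 16_300

    def years_to_generations(self, years: float) -> float:
        return years * self.generations_per_year

    def generations_to_years(self, gens: float) -> float:
        return gens / self.generations_per_year


@dataclass
class DemographicModel:
    name: str
    demes: list[DemeSpec]
    joins: list[JoinEvent]
    bottlenecks: list[BottleneckSpec]
    clock: ClockConfig
    #: "all" applies bottlenecks to every deme extant in the window;
    #: "root" restricts them to the final ancestral deme.
    bottleneck_scope: str = "all"
    #: when True, a single severity draw is shared by all bottlenecks
    shared_severity: bool = False

    @property
    def deme_ids(self) -> list[str]:
        return [d.deme_id for d in self.demes]

    def deme(self, deme_id: str) -> DemeSpec:
        for d in self.demes:
            if d.deme_id == deme_id:
                return d
        raise KeyError(deme_id)


@dataclass(frozen=True)
class ModelParams:
    """One concrete draw: per-bottleneck (onset years BP, severity b)."""

    model_name: str
    bottleneck_draws: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for label, (onset, b) in self.bottleneck_draws.items():
            key = label.lower()
            out[f"{key}_onset_years_bp"] = onset
            out[f"{key}_severity"] = b
        return out


# ---------------------------------------------------------------------------
# packaged default configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The packaged default model configuration.

    13 demes across 5 clades, 113 samples (59 ancient at 14-50 ka BP plus 54
    modern), equal N_ef per deme anchored to the mitochondrial skyline
    plateau (~90,000 females), intra-clade joins completing at the clade
    mrca estimates and a ladder of inter-clade joins rooting at 100 ka BP.
    Every value may be overridden via the configuration document.
    """
    demes = [
        # clade 1 (mrca ~56.5 ka BP)
        dict(deme_id="c1_early", clade="1", age=48_000, n=4),
        dict(deme_id="c1_mid", clade="1", age=40_000, n=4),
        dict(deme_id="c1_late", clade="1", age=32_000, n=4),
        # clade 2
        dict(deme_id="c2_early", clade="2", age=42_000, n=4),
        dict(deme_id="c2_late", clade="2", age=30_000, n=4),
        # clade 3 (mrca ~56.5 ka BP)
        dict(deme_id="c3_early", clade="3", age=50_000, n=4),
        dict(deme_id="c3_mid", clade="3", age=38_000, n=4),
        dict(deme_id="c3_late", clade="3", age=28_000, n=4),
        # clade 4
        dict(deme_id="c4_early", clade="4", age=36_000, n=4),
        dict(deme_id="c4_late", clade="4", age=24_000, n=4),
        # clade 5: the extant clade (mrca ~27 ka BP); 59 ancient + 54 modern
        dict(deme_id="c5_ancient", clade="5", age=14_000, n=19),
        dict(deme_id="c5_modern_w", clade="5", age=0, n=27),
        dict(deme_id="c5_modern_e", clade="5", age=0, n=27),
    ]
    for d in demes:
        d["size_females"] = 90_000.0
    joins = [
        # intra-clade, completing at the clade mrca
        dict(time=44_000, source="c1_late", dest="c1_mid"),
        dict(time=56_500, source="c1_mid", dest="c1_early"),
        dict(time=50_000, source="c2_late", dest="c2_early"),
        dict(time=42_000, source="c3_late", dest="c3_mid"),
        dict(time=56_500, source="c3_mid", dest="c3_early"),
        dict(time=45_000, source="c4_late", dest="c4_early"),
        dict(time=10_000, source="c5_modern_e", dest="c5_modern_w"),
        dict(time=27_000, source="c5_ancient", dest="c5_modern_w"),
        # inter-clade ladder rooting at 100 ka BP
        dict(time=65_000, source="c4_early", dest="c3_early"),
        dict(time=70_000, source="c2_early", dest="c1_early"),
        dict(time=80_000, source="c3_early", dest="c1_early"),
        dict(time=100_000, source="c5_modern_w", dest="c1_early"),
    ]
    bottlenecks = {
        "LGM": dict(
            timing_prior=dict(kind="log-uniform", lower=20_000, upper=30_000),
            severity_prior=dict(kind="uniform", lower=0.2, upper=0.6),
            duration=DEFAULT_DURATIONS["LGM"],
        ),
        "Eemian": dict(
            timing_prior=dict(kind="log-uniform", lower=115_000, upper=130_000),
            severity_prior=dict(kind="uniform", lower=0.2, upper=0.6),
            duration=DEFAULT_DURATIONS["Eemian"],
        ),
    }
    clock = dict(
        generations_per_year=2.0,
        mu_per_site_per_gen=1.035e-7,
        seq_length=16_300,
    )
    return dict(
        demes=demes,
        joins=joins,
        bottlenecks=bottlenecks,
        clock=clock,
        bottleneck_scope="all",
        shared_severity=False,
    )


def config_to_yaml(config: dict | None = None) -> str:
    """Serialise a configuration (default if None) as a YAML document."""
    return yaml.safe_dump(config or default_config(), sort_keys=False)


def config_from_yaml(text: str) -> dict:
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration document must be a mapping")
    return cfg


def _prior_from_dict(d: dict) -> Prior:
    return Prior(kind=d["kind"], lower=float(d["lower"]),
                 upper=(None if d.get("upper") is None else float(d["upper"])))


def build_model(name: str, config: dict | None = None) -> DemographicModel:
    """Build and validate one of the four demographic scenarios.

    Parameters
    ----------
    name
        One of ``constant``, ``lgm``, ``eemian``, ``lgm_eemian``.
    config
        A configuration mapping with sections ``demes``, ``joins``,
        ``bottlenecks``, ``clock`` (see :func:`default_config`); the
        packaged default is used if None.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {SCENARIOS}"
        )
    cfg = copy.deepcopy(config) if config is not None else default_config()
    demes = [
        DemeSpec(
            deme_id=str(d["deme_id"]),
            clade_label=str(d["clade"]),
            sampling_time=float(d["age"]),
            n_samples=int(d["n"]),
            size_females=float(d["size_females"]),
        )
        for d in cfg["demes"]
    ]
    joins = [
        JoinEvent(time=float(j["time"]), source_deme=str(j["source"]),
                  dest_deme=str(j["dest"]))
        for j in cfg["joins"]
    ]
    wanted = {"constant": [], "lgm": ["LGM"], "eemian": ["Eemian"],
              "lgm_eemian": ["LGM", "Eemian"]}[name]
    bottlenecks = []
    for label in wanted:
        b = cfg["bottlenecks"][label]
        bottlenecks.append(
            BottleneckSpec(
                label=label,
                timing_prior=_prior_from_dict(b["timing_prior"]),
                severity_prior=_prior_from_dict(b["severity_prior"]),
                duration=float(b["duration"]),
            )
        )
    clk = cfg.get("clock", {})
    clock = ClockConfig(
        generations_per_year=float(clk.get("generations_per_year", 2.0)),
        mu_per_site_per_gen=float(clk.get("mu_per_site_per_gen", 1.035e-7)),
        seq_length=int(clk.get("seq_length", 16_300)),
    )
    model = DemographicModel(
        name=name, demes=demes, joins=joins, bottlenecks=bottlenecks,
        clock=clock,
        bottleneck_scope=str(cfg.get("bottleneck_scope", "all")),
        shared_severity=bool(cfg.get("shared_severity", False)),
    )
    violations = validate_model(model)
    if violations:
        raise ValueError("invalid model:\n  " + "\n  ".join(violations))
    return model


def validate_model(model: DemographicModel) -> list[str]:
    """Check every structural invariant; return one message per violation.

    An empty list means the model is valid.  Checks: unique deme ids,
    positive sizes and counts, non-negative finite ages, the join events
    forming a tree that connects all demes into a single root, join times
    later (older) than the sampling times of both demes involved, prior
    sanity, and the scenario's bottleneck-count contract.
    """
    v: list[str] = []
    ids = [d.deme_id for d in model.demes]
    seen = set()
    for i in ids:
        if i in seen:
            v.append(f"duplicated deme_id {i!r}")
        seen.add(i)
    for d in model.demes:
        if not (math.isfinite(d.sampling_time) and d.sampling_time >= 0):
            v.append(f"deme {d.deme_id!r}: sampling_time must be finite and >= 0")
        if d.n_samples < 1:
            v.append(f"deme {d.deme_id!r}: n_samples must be >= 1")
        if not d.size_females > 0:
            v.append(f"deme {d.deme_id!r}: size_females must be > 0")

    id_set = set(ids)
    merged: set[str] = set()
    for j in sorted(model.joins, key=lambda j: j.time):
        for role, deme_id in (("source", j.source_deme), ("dest", j.dest_deme)):
            if deme_id not in id_set:
                v.append(f"join at {j.time}: unknown {role} deme {deme_id!r}")
        if j.source_deme in id_set and j.dest_deme in id_set:
            for deme_id in (j.source_deme, j.dest_deme):
                st = model.deme(deme_id).sampling_time
                if not j.time > st:
                    v.append(
                        f"join at {j.time} involves deme {deme_id!r} sampled "
                        f"at {st} (join must postdate sampling, backward in time)"
                    )
            if j.source_deme in merged:
                v.append(f"deme {j.source_deme!r} is the source of more than one join")
            merged.add(j.source_deme)
    if len(model.joins) != len(ids) - 1:
        v.append(
            f"{len(model.joins)} joins for {len(ids)} demes; a join tree "
            f"requires exactly n_demes - 1"
        )
    elif not v:
        roots = id_set - {j.source_deme for j in model.joins}
        if len(roots) != 1:
            v.append(f"join events leave {len(roots)} root demes, expected 1")

    n_expected = {"constant": 0, "lgm": 1, "eemian": 1, "lgm_eemian": 2}.get(
        model.name
    )
    if n_expected is None:
        v.append(f"unknown scenario name {model.name!r}")
    elif len(model.bottlenecks) != n_expected:
        v.append(
            f"scenario {model.name!r} must carry {n_expected} bottlenecks, "
            f"found {len(model.bottlenecks)}"
        )
    for b in model.bottlenecks:
        if b.severity_prior.kind != "fixed":
            if not (0 < b.severity_prior.lower and b.severity_prior.upper <= 1):
                v.append(f"bottleneck {b.label!r}: severity bounds must lie in (0, 1]")
        if b.timing_prior.lower <= 0:
            v.append(f"bottleneck {b.label!r}: timing prior bounds must be positive")
        if b.duration <= 0:
            v.append(f"bottleneck {b.label!r}: duration must be positive")
    if model.bottleneck_scope not in ("all", "root"):
        v.append(f"bottleneck_scope must be 'all' or 'root', got {model.bottleneck_scope!r}")

    for fname, val in (
        ("generations_per_year", model.clock.generations_per_year),
        ("seq_length", model.clock.seq_length),
    ):
        if not val > 0:
            v.append(f"clock.{fname} must be strictly positive")
    if model.clock.mu_per_site_per_gen < 0:
        v.append("clock.mu_per_site_per_gen must be non-negative")
    return v


def draw_params(model: DemographicModel, rng: np.random.Generator) -> ModelParams:
    """Draw one parameter set from the model's priors.

    The constant scenario has no free parameters (severity implicitly 1.0).
    With ``shared_severity`` a single severity draw is reused for every
    bottleneck.
    """
    draws: dict[str, tuple[float, float]] = {}
    shared_b: float | None = None
    for b in model.bottlenecks:
        onset = b.timing_prior.sample(rng)
        if model.shared_severity:
            if shared_b is None:
                shared_b = b.severity_prior.sample(rng)
            sev = shared_b
        else:
            sev = b.severity_prior.sample(rng)
        draws[b.label] = (onset, sev)
    return ModelParams(model_name=model.name, bottleneck_draws=draws)
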
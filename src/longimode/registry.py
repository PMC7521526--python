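"""Variable catalogue for the two-wave brain-behaviour analysis.

Every column that enters any analysis matrix is described by one
:class:`Variable` row: which block it belongs to (imaging-derived
phenotype or behavioural), its domain and subdomain, whether it is a
raw change score, a raw average score, or a single/cross-sectional
measure, and its trait polarity (whether larger values mean better
function, which decides sign inversion before scoring).

The default full-scale registry reproduces the dimensions of the
cohort the pipeline is modelled on: 454 longitudinal IDPs grouped
into six image-processing subdomains (139 FAST grey-matter ROIs,
15 FIRST subcortical structures, 10 SIENAX global volumes, 1 SIENA
percentage brain-volume change, 1 BIANCA white-matter-hyperintensity
volume, 288 TBSS diffusion measures) and 114 behavioural variables
(64 cognitive = 33 change + 27 average + 4 IQ scores, plus 8
demographic, 34 health and 8 lifestyle measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

BLOCKS = ("IDP", "behavioural")
DOMAINS = ("cognitive", "demographic", "health", "lifestyle", "IDP")
SCORE_KINDS = ("cross_sectional_W57", "cross_sectional_W63", "change", "average", "single")
POLARITIES = ("higher_is_better", "lower_is_better", "neutral")
WAVES = ("W57", "W63")

#: IDP subdomain -> (count at W57, count at W63); W63 column totals 454.
IDP_SUBDOMAIN_SIZES = {
    "FAST-GM-ROI": (139, 139),
    "FIRST-subcortical": (15, 15),
    "SIENAX-global": (10, 10),
    "SIENA-PBVC": (0, 1),
    "BIANCA-WMH": (1, 1),
    "TBSS-dMRI": (288, 288),
}

CHANGE_SUFFIX = "__chg"
AVERAGE_SUFFIX = "__avg"


@dataclass(frozen=True)
class Variable:
    """One analysis variable (a column of an analysis matrix)."""

    id: str
    block: str
    domain: str
    subdomain: str
    score_kind: str
    trait_polarity: str
    waves_present: frozenset = frozenset()
    #: id of the underlying repeated measurement for change/average scores;
    #: equals ``id`` for single and cross-sectional variables.
    source: str = ""

    def __post_init__(self):
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score_kind {self.score_kind!r}")
        if self.trait_polarity not in POLARITIES:
            raise ValueError(f"unknown trait_polarity {self.trait_polarity!r}")
        if self.score_kind in ("change", "average") and self.waves_present != frozenset(WAVES):
            raise ValueError(
                f"{self.id}: {self.score_kind} score requires both waves present"
            )
        if not self.source:
            object.__setattr__(self, "source", self.id)


@dataclass
class VariableRegistry:
    """Catalogue of analysis variables plus the cross-sectional selections.

    ``variables`` holds one row per column of the *longitudinal* analysis
    matrices (454 IDP + 114 behavioural at full scale).  The cross-sectional
    analysis sets are views over the underlying source measurements:
    ``xs_idp_sources`` (453 at full scale) and ``xs_behavioural_sources``
    (70 at full scale).
    """

    variables: list = field(default_factory=list)
    xs_idp_sources: list = field(default_factory=list)
    xs_behavioural_sources: list = field(default_factory=list)

    def __post_init__(self):
        ids = [v.id for v in self.variables]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variable ids: {dupes[:5]}")
        self._by_id = {v.id: v for v in self.variables}

    # -- lookups ---------------------------------------------------------
    def __len__(self):
        return len(self.variables)

    def __contains__(self, var_id):
        return var_id in self._by_id

    def __getitem__(self, var_id) -> Variable:
        return self._by_id[var_id]

    def ids(self, block=None, domain=None, subdomain=None, score_kind=None):
        """Ids of analysis variables matching the given filters, in registry order."""
        out = []
        for v in self.variables:
            if block is not None and v.block != block:
                continue
            if domain is not None and v.domain != domain:
                continue
            if subdomain is not None and v.subdomain != subdomain:
                continue
            if score_kind is not None and v.score_kind != score_kind:
                continue
            out.append(v.id)
        return out

    def source_ids(self, block, wave):
        """Underlying measurement ids of ``block`` observed at ``wave`` (deduplicated)."""
        seen, out = set(), []
        for v in self.variables:
            if v.block != block or wave not in v.waves_present:
                continue
            if v.source not in seen:
                seen.add(v.source)
                out.append(v.source)
        return out

    def subdomains(self, block):
        seen, out = set(), []
        for v in self.variables:
            if v.block == block and v.subdomain not in seen:
                seen.add(v.subdomain)
                out.append(v.subdomain)
        return out

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": v.id,
                "block": v.block,
                "domain": v.domain,
                "subdomain": v.subdomain,
                "score_kind": v.score_kind,
                "trait_polarity": v.trait_polarity,
                "waves_present": ",".join(sorted(v.waves_present)),
                "source": v.source,
            }
            for v in self.variables
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path):
        df = self.to_frame()
        df["xs"] = [
            v.source in set(self.xs_idp_sources) or v.source in set(self.xs_behavioural_sources)
            for v in self.variables
        ]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "VariableRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        variables = [
            Variable(
                id=r["id"],
                block=r["block"],
                domain=r["domain"],
                subdomain=r["subdomain"],
                score_kind=r["score_kind"],
                trait_polarity=r["trait_polarity"],
                waves_present=frozenset(w for w in r["waves_present"].split(",") if w),
                source=r["source"],
            )
            for r in df.to_dict("records")
        ]
        reg = cls(variables)
        if "xs" in df.columns:
            flagged = set(df.loc[df["xs"].str.lower() == "true", "source"])
            reg.xs_idp_sources = [s for s in reg.source_ids("IDP", "W57") if s in flagged]
            reg.xs_behavioural_sources = _xs_behavioural(reg, flagged)
        return reg


def _xs_behavioural(reg, flagged):
    seen, out = set(), []
    for v in reg.variables:
        if v.block != "behavioural":
            continue
        if v.source in flagged and v.source not in seen:
            seen.add(v.source)
            out.append(v.source)
    return out


# ---------------------------------------------------------------------------
# default registry construction


def _idp_variables(scale: dict) -> list:
    """One longitudinal analysis row per IDP: change scores for repeated
    measurements, plus the inherently longitudinal SIENA PBVC (W63 only)."""
    out = []
    for sub, n in scale.items():
        tag = sub.lower().replace("-", "_")
        for i in range(n):
            base = f"idp_{tag}_{i + 1:03d}"
            if sub == "SIENA-PBVC":
                out.append(
                    Variable(base, "IDP", "IDP", sub, "single", "neutral",
                             frozenset({"W63"}))
                )
            else:
                out.append(
                    Variable(base + CHANGE_SUFFIX, "IDP", "IDP", sub, "change",
                             "neutral", frozenset(WAVES), source=base)
                )
    return out


def _behavioural_variables(counts: dict) -> list:
    """Behavioural rows honouring the change/average/IQ split.

    ``counts`` keys: cog_change_only, cog_change_avg, n_iq, demographic,
    health_repeated, health_single, lifestyle.  Cognitive change totals
    cog_change_only + cog_change_avg; averages total cog_change_avg.
    """
    out = []
    both = frozenset(WAVES)
    # Repeated cognitive tests; speed/error-type tests are lower-is-better.
    n_cog = counts["cog_change_only"] + counts["cog_change_avg"]
    for i in range(n_cog):
        base = f"cog_test_{i + 1:02d}"
        pol = "lower_is_better" if i % 3 == 0 else "higher_is_better"
        out.append(Variable(base + CHANGE_SUFFIX, "behavioural", "cognitive",
                            "CANTAB", "change", pol, both, source=base))
        if i < counts["cog_change_avg"]:
            out.append(Variable(base + AVERAGE_SUFFIX, "behavioural", "cognitive",
                                "CANTAB", "average", pol, both, source=base))
    # Early-life IQ scores travel with the baseline file; late-midlife IQ
    # scores are wave-specific cross-sectional measures.
    iq_rows = [("iq_11", "single", "W57"), ("iq_20", "single", "W57"),
               ("iq_57", "cross_sectional_W57", "W57"),
               ("iq_63", "cross_sectional_W63", "W63")]
    for name, kind, w in iq_rows[: counts["n_iq"]]:
        out.append(Variable(name, "behavioural", "cognitive", "IQ",
                            kind, "higher_is_better", frozenset({w})))
    for i in range(counts["demographic"]):
        out.append(Variable(f"demo_{i + 1:02d}", "behavioural", "demographic",
                            "socio-demographic", "cross_sectional_W63",
                            "neutral", frozenset({"W63"})))
    for i in range(counts["health_repeated"]):
        base = f"health_rep_{i + 1:02d}"  # BMI and lipid panel style measures
        out.append(Variable(base + CHANGE_SUFFIX, "behavioural", "health", "lipids",
                            "change", "lower_is_better", both, source=base))
        out.append(Variable(base + AVERAGE_SUFFIX, "behavioural", "health", "lipids",
                            "average", "lower_is_better", both, source=base))
    for i in range(counts["health_single"]):
        pol = "lower_is_better" if i % 2 == 0 else "neutral"
        out.append(Variable(f"health_{i + 1:02d}", "behavioural", "health",
                            "general-health", "cross_sectional_W63", pol,
                            frozenset({"W63"})))
    for i in range(counts["lifestyle"]):
        out.append(Variable(f"life_{i + 1:02d}", "behavioural", "lifestyle",
                            "lifestyle", "cross_sectional_W63",
                            "higher_is_better", frozenset({"W63"})))
    return out


FULL_BEH_COUNTS = {
    # 33 change + 27 average + 4 IQ = 64 cognitive
    "cog_change_only": 6,
    "cog_change_avg": 27,
    "n_iq": 4,
    "demographic": 8,
    # 5 repeated measures (BMI + 4 lipids) contribute change+average = 10,
    # plus 24 single health measures = 34 health
    "health_repeated": 5,
    "health_single": 24,
    "lifestyle": 8,
}

TOY_IDP_SIZES = {
    "FAST-GM-ROI": 12,
    "FIRST-subcortical": 4,
    "SIENAX-global": 3,
    "SIENA-PBVC": 1,
    "BIANCA-WMH": 1,
    "TBSS-dMRI": 19,
}

TOY_BEH_COUNTS = {
    "cog_change_only": 2,
    "cog_change_avg": 4,
    "n_iq": 2,
    "demographic": 2,
    "health_repeated": 1,
    "health_single": 2,
    "lifestyle": 2,
}


def build_default_registry(profile: str = "full") -> VariableRegistry:
    """Build the default variable catalogue.

    Parameters
    ----------
    profile:
        ``"full"`` reproduces the cohort's dimensions (454 IDPs, 114
        behavioural variables); ``"toy"`` scales every subdomain down
        proportionally (40 IDPs, 20 behavioural) for fast tests.
    """
    if profile == "full":
        idp_sizes = {k: v[1] for k, v in IDP_SUBDOMAIN_SIZES.items()}
        beh_counts = FULL_BEH_COUNTS
    elif profile == "toy":
        idp_sizes = TOY_IDP_SIZES
        beh_counts = TOY_BEH_COUNTS
    else:
        raise ValueError(f"unknown profile {profile!r}")

    variables = _idp_variables(idp_sizes) + _behavioural_variables(beh_counts)
    reg = VariableRegistry(variables)
    reg.xs_idp_sources = reg.source_ids("IDP", "W57")
    reg.xs_behavioural_sources = _default_xs_behavioural(reg, profile)
    return reg


def _default_xs_behavioural(reg, profile):
    """Cross-sectional behavioural selection.

    The cohort analyses 70 cross-sectional behavioural items; the exact
    membership is a reporting convention, realised here as: all repeated
    cognitive tests (33), the two wave-specific IQ scores, all demographic
    and lifestyle measures, the repeated health measures and enough single
    health measures to complete the set (19 health total at full scale).
    """
    n_target = 70 if profile == "full" else 12
    chosen = []
    chosen += [v for v in reg.source_ids("behavioural", "W57") if v.startswith("cog_test")]
    chosen += [i for i in ("iq_57", "iq_63") if i in reg]
    chosen += reg.ids(block="behavioural", domain="demographic")
    chosen += reg.ids(block="behavioural", domain="lifestyle")
    chosen += [s for s in reg.source_ids("behavioural", "W63") if s.startswith("health_rep")]
    singles = reg.ids(block="behavioural", domain="health", score_kind="cross_sectional_W63")
    chosen += singles[: max(0, n_target - len(chosen))]
    # canonical order: registry enumeration order (stable under round trips)
    return _xs_behavioural(reg, set(chosen[:n_target]))
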
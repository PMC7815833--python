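"""Arm usage ratio (AUR), arm dominance, overall arm preference (OAP) and
arm-switch detection.

AUR = 5p / (5p + 3p) over read counts.  Dominance: AUR > 0.7 -> 5p
dominant, AUR < 0.3 -> 3p dominant, the closed interval [0.3, 0.7] -> no
preference; samples below the expression floor are 'no expression'.  The
OAP of a miRNA is the dominance type shown by strictly more than 70% of
its informative tissue samples.  A switch is a swap of the dominant arm
(5p vs 3p, never dominance-vs-no-preference) between species, tissues, or
paralogues.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LABELS = ("dominant_5p", "dominant_3p", "no_preference", "no_expression")


@dataclass
class PreferenceConfig:
    aur_high: float = 0.7
    aur_low: float = 0.3
    oap_fraction: float = 0.7
    min_reads: int = 10
    # whether no-expression samples enter the OAP denominator; informative-only
    # is the default since a silent tissue says nothing about arm choice
    count_no_expression: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.aur_low < self.aur_high <= 1):
            raise ValueError(
                f"need 0 <= aur_low < aur_high <= 1, got {self.aur_low}, {self.aur_high}"
            )
        if not (0 < self.oap_fraction < 1):
            raise ValueError(f"oap_fraction must be in (0,1), got {self.oap_fraction}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


@dataclass
class ArmCall:
    locus_id: str
    sample_id: str
    aur: float | None
    label: str


@dataclass
class OapRecord:
    locus_id: str
    oap: str  # '5p', '3p' or 'undefined'
    support_fraction: float
    n_informative_samples: int


@dataclass(frozen=True)
class SwitchEvent:
    kind: str  # species_switch | tissue_switch | paralogue_switch
    entity_a: str
    entity_b: str
    arm_a: str
    arm_b: str

    def __post_init__(self) -> None:
        if self.arm_a == self.arm_b:
            raise ValueError("a switch requires opposite arms")


def compute_aur(
    count_5p: float,
    count_3p: float,
    cfg: PreferenceConfig | None = None,
    locus_id: str = "",
    sample_id: str = "",
) -> ArmCall:
    """AUR and dominance label for one (locus, sample) count pair."""
    cfg = cfg or PreferenceConfig()
    if count_5p < 0 or count_3p < 0:
        raise ValueError(f"negative arm count ({count_5p}, {count_3p})")
    total = count_5p + count_3p
    if total < cfg.min_reads or total == 0:
        return ArmCall(locus_id, sample_id, None, "no_expression")
    aur = count_5p / total
    if aur > cfg.aur_high:
        label = "dominant_5p"
    elif aur < cfg.aur_low:
        label = "dominant_3p"
    else:
        label = "no_preference"
    return ArmCall(locus_id, sample_id, aur, label)


def overall_arm_preference(
    calls: list[ArmCall], cfg: PreferenceConfig | None = None
) -> OapRecord:
    """OAP over one locus's calls across samples.

    The dominance type (5p or 3p) whose share of the denominator strictly
    exceeds ``oap_fraction`` is the OAP; otherwise no OAP is defined.
    Fewer than two informative samples -> undefined.
    """
    cfg = cfg or PreferenceConfig()
    if not calls:
        raise ValueError("overall_arm_preference needs at least one call")
    locus_id = calls[0].locus_id
    informative = [c for c in calls if c.label != "no_expression"]
    denom_calls = calls if cfg.count_no_expression else informative
    n_inf = len(informative)
    if n_inf < 2 or not denom_calls:
        return OapRecord(locus_id, "undefined", 0.0, n_inf)
    denom = len(denom_calls)
    share_5p = sum(1 for c in denom_calls if c.label == "dominant_5p") / denom
    share_3p = sum(1 for c in denom_calls if c.label == "dominant_3p") / denom
    if share_5p > cfg.oap_fraction:
        return OapRecord(locus_id, "5p", share_5p, n_inf)
    if share_3p > cfg.oap_fraction:
        return OapRecord(locus_id, "3p", share_3p, n_inf)
    return OapRecord(locus_id, "undefined", max(share_5p, share_3p), n_inf)


def preference_state(rec: OapRecord) -> str:
    """Fig-style per-entity state: 5p / 3p / none / no_expression."""
    if rec.oap in ("5p", "3p"):
        return rec.oap
    return "no_expression" if rec.n_informative_samples == 0 else "none"


def detect_species_switching(
    oap_by_species: dict[str, dict[str, OapRecord]],
) -> tuple[list[SwitchEvent], pd.DataFrame, list[tuple[str, str, str]]]:
    """Cross-species arm-switch scan.

    ``oap_by_species`` maps entity (family/orthologue) -> species -> OAP.
    Emits a species_switch for every species pair with defined, opposite
    OAPs; pairs where either side is undefined are listed as
    discordant-uncallable, not switches.  Also returns the full entity x
    species preference matrix with states {5p, 3p, none, no_expression}.
    """
    events: list[SwitchEvent] = []
    uncallable: list[tuple[str, str, str]] = []
    species = sorted({sp for recs in oap_by_species.values() for sp in recs})
    matrix_rows = {}
    for entity in sorted(oap_by_species):
        recs = oap_by_species[entity]
        matrix_rows[entity] = {
            sp: (preference_state(recs[sp]) if sp in recs else "no_expression")
            for sp in species
        }
        present = sorted(recs)
        for i, sp_a in enumerate(present):
            for sp_b in present[i + 1 :]:
                a, b = recs[sp_a].oap, recs[sp_b].oap
                if a in ("5p", "3p") and b in ("5p", "3p"):
                    if a != b:
                        events.append(
                            SwitchEvent(
                                "species_switch",
                                f"{entity}:{sp_a}",
                                f"{entity}:{sp_b}",
                                a,
                                b,
                            )
                        )
                elif "undefined" in (a, b) and (a in ("5p", "3p") or b in ("5p", "3p")):
                    uncallable.append((entity, sp_a, sp_b))
    matrix = pd.DataFrame.from_dict(matrix_rows, orient="index", columns=species)
    matrix.index.name = "entity"
    return events, matrix, uncallable


def detect_within_species_switching(
    calls_by_locus: dict[str, list[ArmCall]],
    paralogue_oaps: dict[str, dict[str, OapRecord]] | None = None,
) -> list[SwitchEvent]:
    """Tissue/stage switches within loci and paralogue switches within
    families.

    ``calls_by_locus``: locus -> per-sample calls; a tissue_switch is
    emitted per locus pairing one 5p-dominant and one 3p-dominant sample
    (first of each in sample order).  ``paralogue_oaps``: family ->
    paralogue locus -> OAP within one species; every pair of paralogues
    with defined, opposite OAPs is a paralogue_switch.
    """
    events: list[SwitchEvent] = []
    for locus_id in sorted(calls_by_locus):
        calls = calls_by_locus[locus_id]
        first_5p = next((c for c in calls if c.label == "dominant_5p"), None)
        first_3p = next((c for c in calls if c.label == "dominant_3p"), None)
        if first_5p is not None and first_3p is not None:
            events.append(
                SwitchEvent(
                    "tissue_switch",
                    f"{locus_id}:{first_5p.sample_id}",
                    f"{locus_id}:{first_3p.sample_id}",
                    "5p",
                    "3p",
                )
            )
    if paralogue_oaps:
        for family_id in sorted(paralogue_oaps):
            recs = paralogue_oaps[family_id]
            loci = sorted(recs)
            for i, la in enumerate(loci):
                for lb in loci[i + 1 :]:
                    a, b = recs[la].oap, recs[lb].oap
                    if a in ("5p", "3p") and b in ("5p", "3p") and a != b:
                        events.append(
                            SwitchEvent("paralogue_switch", la, lb, a, b)
                        )
    return events


def family_oaps_from_counts(
    counts: pd.DataFrame,
    locus_info: dict[str, tuple[str, str]],
    cfg: PreferenceConfig | None = None,
):
    """Family-level and per-paralogue OAPs from an arm-count table.

    ``locus_info`` maps locus_id -> (family_id, species_id).  Family-level
    counts pool paralogues per sample before the AUR (paralogues commonly
    share arm sequence, so pooled counts mirror per-miRNA mapping);
    per-paralogue OAPs keep loci separate for paralogue-switch detection.
    Returns ``(fam_oaps, para_oaps)``: family -> species -> OapRecord and
    family -> species -> locus -> OapRecord.
    """
    cfg = cfg or PreferenceConfig()
    counts = counts.copy()
    counts["family_id"] = counts["locus_id"].map(lambda x: locus_info[x][0])
    counts["species_id"] = counts["locus_id"].map(lambda x: locus_info[x][1])

    fam_oaps: dict[str, dict[str, OapRecord]] = {}
    pooled = counts.groupby(["family_id", "species_id", "sample_id"], sort=True)[
        ["count_5p", "count_3p"]
    ].sum()
    for (fam, sp), grp in pooled.groupby(level=[0, 1]):
        calls = [
            compute_aur(r.count_5p, r.count_3p, cfg, fam, idx[2])
            for idx, r in zip(grp.index, grp.itertuples(index=False))
        ]
        fam_oaps.setdefault(fam, {})[sp] = overall_arm_preference(calls, cfg)

    para_oaps: dict[str, dict[str, dict[str, OapRecord]]] = {}
    for (fam, sp, lid), grp in counts.groupby(
        ["family_id", "species_id", "locus_id"], sort=True
    ):
        calls = [
            compute_aur(r.count_5p, r.count_3p, cfg, lid, r.sample_id)
            for r in grp.itertuples(index=False)
        ]
        para_oaps.setdefault(fam, {}).setdefault(sp, {})[lid] = (
            overall_arm_preference(calls, cfg)
        )
    return fam_oaps, para_oaps


def calls_from_count_table(
    counts: pd.DataFrame, cfg: PreferenceConfig | None = None
) -> pd.DataFrame:
    """Vector AUR/dominance over an arm-count table; returns a calls table
    with columns locus_id, sample_id, aur, label."""
    cfg = cfg or PreferenceConfig()
    rows = []
    for rec in counts.itertuples(index=False):
        call = compute_aur(rec.count_5p, rec.count_3p, cfg, rec.locus_id, rec.sample_id)
        rows.append(
            {
                "locus_id": call.locus_id,
                "sample_id": call.sample_id,
                "aur": call.aur,
                "label": call.label,
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "sample_id", "aur", "label"])
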
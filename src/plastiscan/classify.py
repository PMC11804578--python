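"""Gene-category decision rules on the contrast catalog.

All rules operate on a *calls frame* — one ternary call column per contrast,
indexed by gene — so the very same rule functions can be evaluated on
independently permuted columns to estimate chance expectations.

Sign conventions: plasticity calls are treatment over control; divergence
calls are mine over coast. "Shared" means both populations of an ecotype
carry a significant call in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .contrasts import ContrastCatalog

CATEGORIES = (
    "preadaptive",
    "cue_transfer",
    "genetic_adoption",
    "genetic_assimilation",
    "evolved_plasticity_unclassified",
    "constitutive_unclassified",
    "none",
)

_COASTS = ("Coast-W", "Coast-E")
_MINES = ("Mine-W", "Mine-E")


def shared_direction(frame: pd.DataFrame, col_a: str, col_b: str) -> pd.Series:
    """Per-gene shared direction of two call columns ("ns" when not shared)."""
    a, b = frame[col_a], frame[col_b]
    shared = (a == b) & a.isin(["up", "down"])
    return pd.Series(np.where(shared, a, "ns"), index=frame.index)


def coast_salt_shared(frame):
    return shared_direction(frame, "P:Coast-W:salt", "P:Coast-E:salt")


def mine_salt_shared(frame):
    return shared_direction(frame, "P:Mine-W:salt", "P:Mine-E:salt")


def coast_zinc_shared(frame):
    return shared_direction(frame, "P:Coast-W:zinc", "P:Coast-E:zinc")


def mine_zinc_shared(frame):
    return shared_direction(frame, "P:Mine-W:zinc", "P:Mine-E:zinc")


def constitutive_ec_direction(frame: pd.DataFrame) -> pd.Series:
    """Shared mine-vs-coast control divergence direction ("ns" otherwise)."""
    return shared_direction(frame, "D:W:control", "D:E:control")


def evolved_zinc_plasticity_mask(frame: pd.DataFrame) -> pd.Series:
    """Shared mine zinc plasticity AND mine/coast divergence in the zinc
    treatment significant in both pairs."""
    mz = mine_zinc_shared(frame) != "ns"
    d_both = (frame["D:W:zinc"] != "ns") & (frame["D:E:zinc"] != "ns")
    return mz & d_both


def changed_plasticity_mask(frame: pd.DataFrame) -> pd.Series:
    """Evolved-zinc-plasticity genes whose shared coastal zinc call differs
    (in significance or direction) from the shared mine zinc call."""
    return evolved_zinc_plasticity_mask(frame) & (
        coast_zinc_shared(frame) != mine_zinc_shared(frame)
    )


def preadaptive_mask(frame: pd.DataFrame) -> pd.Series:
    """Significant same-direction salt AND zinc responses in all four
    populations."""
    cols = [f"P:{p}:{c}" for p in _COASTS + _MINES for c in ("salt", "zinc")]
    first = frame[cols[0]]
    ok = first.isin(["up", "down"])
    for c in cols[1:]:
        ok &= frame[c] == first
    return ok


def cue_transfer_mask(frame: pd.DataFrame) -> pd.Series:
    """Shared coastal salt response whose direction reappears as evolved mine
    zinc plasticity, while the shared coastal zinc response is absent or
    different."""
    d_s = coast_salt_shared(frame)
    cz = coast_zinc_shared(frame)
    mz = mine_zinc_shared(frame)
    return (
        (d_s != "ns")
        & (cz != d_s)
        & evolved_zinc_plasticity_mask(frame)
        & (mz == d_s)
    )


def genetic_adoption_mask(frame: pd.DataFrame) -> pd.Series:
    """Shared coastal salt response made constitutive: matching shared
    control divergence, no mine zinc plasticity in either mine, and no
    matching coastal zinc response."""
    d_s = coast_salt_shared(frame)
    ec = constitutive_ec_direction(frame)
    cz = coast_zinc_shared(frame)
    mine_ns = (frame["P:Mine-W:zinc"] == "ns") & (frame["P:Mine-E:zinc"] == "ns")
    return (d_s != "ns") & (ec == d_s) & mine_ns & (cz != d_s)


def genetic_assimilation_mask(frame: pd.DataFrame) -> pd.Series:
    """Ancestral zinc plasticity canalized: shared control divergence in the
    shared coastal-zinc direction with mine zinc plasticity lost."""
    ec = constitutive_ec_direction(frame)
    cz = coast_zinc_shared(frame)
    mine_ns = (frame["P:Mine-W:zinc"] == "ns") & (frame["P:Mine-E:zinc"] == "ns")
    return (ec != "ns") & (cz == ec) & mine_ns


@dataclass
class ClassificationReport:
    """Per-gene category with the evidence tuple, plus set sizes."""

    genes: pd.DataFrame  # gene_id, category, evidence columns
    sizes: dict
    alpha: float

    def category_counts(self) -> pd.Series:
        return self.genes["category"].value_counts().reindex(CATEGORIES, fill_value=0)


def classify(catalog: ContrastCatalog) -> ClassificationReport:
    """Assign every comparable gene to a category.

    The four principal categories are provably pairwise disjoint under the
    rules; this is re-checked at run time and any overlap aborts with a
    diagnostic rather than silently picking a label.
    """
    frame = catalog.frame()
    cs, ms = coast_salt_shared(frame), mine_salt_shared(frame)
    cz, mz = coast_zinc_shared(frame), mine_zinc_shared(frame)
    ec = constitutive_ec_direction(frame)
    evolved = evolved_zinc_plasticity_mask(frame)
    changed = changed_plasticity_mask(frame)
    masks = {
        "preadaptive": preadaptive_mask(frame),
        "cue_transfer": cue_transfer_mask(frame),
        "genetic_adoption": genetic_adoption_mask(frame),
        "genetic_assimilation": genetic_assimilation_mask(frame),
    }
    overlap = sum(m.astype(int) for m in masks.values())
    if (overlap > 1).any():
        bad = frame.index[overlap > 1].tolist()
        raise RuntimeError(
            f"genes assigned to multiple principal categories: {bad[:10]}"
        )
    category = pd.Series("none", index=frame.index)
    for name, mask in masks.items():
        category[mask] = name
    unassigned = category == "none"
    category[unassigned & evolved] = "evolved_plasticity_unclassified"
    unassigned = category == "none"
    category[unassigned & (ec != "ns")] = "constitutive_unclassified"

    genes = pd.DataFrame(
        {
            "gene_id": frame.index,
            "category": category.to_numpy(),
            "coast_salt_shared": cs.to_numpy(),
            "mine_salt_shared": ms.to_numpy(),
            "coast_zinc_shared": cz.to_numpy(),
            "mine_zinc_shared": mz.to_numpy(),
            "ec_direction": ec.to_numpy(),
            "d_zinc_both_sig": (
                (frame["D:W:zinc"] != "ns") & (frame["D:E:zinc"] != "ns")
            ).to_numpy(),
            "evolved_zinc_plasticity": evolved.to_numpy(),
            "changed_plasticity": changed.to_numpy(),
        }
    ).reset_index(drop=True)

    salt_overlap = int(((ms != "ns") & (ms == cs)).sum())
    sizes = {
        "CoastSaltPlastic": int((cs != "ns").sum()),
        "MineSaltPlastic": int((ms != "ns").sum()),
        "CoastZincPlastic": int((cz != "ns").sum()),
        "MineZincPlastic": int((mz != "ns").sum()),
        "EvolvedZincPlasticity": int(evolved.sum()),
        "ChangedPlasticity": int(changed.sum()),
        "ConstitutiveEC": int((ec != "ns").sum()),
        "SaltPlasticOverlap": salt_overlap,
        "universe": int(len(frame)),
    }
    for name, mask in masks.items():
        sizes[name] = int(mask.sum())
    return ClassificationReport(genes=genes, sizes=sizes, alpha=catalog.alpha)


def expand_report(report: ClassificationReport, all_genes) -> pd.DataFrame:
    """Report over a larger gene universe: genes that never reached the
    classifier (filtered out upstream) appear with category "none"."""
    idx = pd.Index(all_genes)
    out = report.genes.set_index("gene_id").reindex(idx)
    out["category"] = out["category"].fillna("none")
    return out.reset_index(names="gene_id")


def _pct(numerator: int, denominator: int, ndigits: int) -> float:
    """Percentage with ties rounded away from zero (exact decimal arithmetic)."""
    if denominator == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    val = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(val)


def summarize_counts(sizes: dict, universe_size: int | None = None) -> pd.DataFrame:
    """Headline percentages from raw set sizes.

    ``sizes`` uses the keys produced by :func:`classify`; missing entries are
    skipped. Integer percentages round half away from zero; two-decimal
    percentages use the same rule at two decimals (this reproduces printed
    values such as 31 from 28/91 and 86.21 from 957 vs 132 retained).
    """
    universe = universe_size if universe_size is not None else sizes.get("universe")
    rows = []

    def add(name, num, den, ndigits):
        if num is None or den is None:
            return
        rows.append(
            dict(
                quantity=name,
                numerator=num,
                denominator=den,
                value=_pct(num, den, ndigits),
            )
        )

    add("cue_transfer_pct_of_changed", sizes.get("cue_transfer"), sizes.get("ChangedPlasticity"), 0)
    add("genetic_adoption_pct_of_ec", sizes.get("genetic_adoption"), sizes.get("ConstitutiveEC"), 0)
    add(
        "genetic_assimilation_pct_of_ec",
        sizes.get("genetic_assimilation"),
        sizes.get("ConstitutiveEC"),
        0,
    )
    overlap = sizes.get("SaltPlasticOverlap")
    add("mine_salt_retention_pct", overlap, sizes.get("MineSaltPlastic"), 0)
    coast_salt = sizes.get("CoastSaltPlastic")
    if overlap is not None and coast_salt:
        add("salt_plasticity_loss_pct", coast_salt - overlap, coast_salt, 2)
    if universe:
        add("coast_salt_transcriptome_pct", coast_salt, universe, 2)
        add("mine_salt_transcriptome_pct", sizes.get("MineSaltPlastic"), universe, 2)
        add("coast_zinc_transcriptome_pct", sizes.get("CoastZincPlastic"), universe, 2)
    return pd.DataFrame(rows)


def summarize_report(
    report: ClassificationReport, universe_size: int | None = None
) -> pd.DataFrame:
    """Headline percentages (counts, fractions) for a classification run."""
    return summarize_counts(report.sizes, universe_size)
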
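"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and an explicit seed
(identical calls give identical output, byte-for-byte when written to disk)
and returns an answer key sufficient to check the downstream stage exactly
(category and overlap counts) or to a stated tolerance (correlations).

What is emulated: paired differential-protein tables with a controlled
overlap and direction-concordance structure; per-protein multi-study signed
report vectors; an abundance matrix with planted correlated modules, one of
which drives a per-sample trait; and flat-colour stain images with an exact
planted positive-pixel fraction inside an ROI. None of it imitates raw mass
spectra, peptide-level quantification or realistic slide artefacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .coexpress import AbundanceMatrix
from .consistency import DirectionCall, score_reports
from .tables_io import DiffRecord, DiffTable, ProteinKey, ReferenceSet

__all__ = [
    "ConcordanceTruth",
    "ModuleTruth",
    "StainImageTruth",
    "gen_disease_tables",
    "gen_category_scenario",
    "plant_reference_set",
    "gen_study_reports",
    "gen_expression",
    "gen_stain_image",
    "write_answer_key",
    "write_png",
    "read_png",
]

# log2 fold-change magnitudes are drawn from this range; the sign carries the
# planted direction, the magnitude is realistic dressing
LOG2FC_RANGE = (0.3, 2.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _protein_key(i: int) -> ProteinKey:
    return ProteinKey(uniprot=f"P{i:05d}", gene=f"GENE{i}")


def _log2fc(rng: np.random.Generator, direction: str) -> float:
    mag = float(rng.uniform(*LOG2FC_RANGE))
    return mag if direction == "up" else -mag


def write_answer_key(key: dict, path) -> None:
    Path(path).write_text(json.dumps(key, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# paired differential tables


@dataclass(frozen=True)
class ConcordanceTruth:
    """Planted structure of a pair of differential tables."""

    n_universe: int = 1000
    n_a: int = 100
    n_b: int = 100
    n_overlap: int = 50
    frac_same_direction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        _require(self.n_overlap <= min(self.n_a, self.n_b), "n_overlap exceeds min(n_a, n_b)")
        _require(max(self.n_a, self.n_b) <= self.n_universe, "table sizes exceed n_universe")
        _require(0 <= self.frac_same_direction <= 1, "frac_same_direction outside [0, 1]")


def gen_disease_tables(truth: ConcordanceTruth) -> tuple[DiffTable, DiffTable, dict]:
    """Two differential tables sharing exactly ``n_overlap`` protein keys.

    Among shared keys, ``round(frac_same_direction * n_overlap)`` carry the
    same direction sign in both tables; the rest are opposite. The answer key
    records every protein's planted category plus the expected concordance
    summary.
    """
    rng = np.random.default_rng(truth.seed)
    ids = rng.permutation(truth.n_universe)
    shared = ids[: truth.n_overlap]
    a_only = ids[truth.n_overlap : truth.n_a]
    b_only = ids[truth.n_a : truth.n_a + (truth.n_b - truth.n_overlap)]
    n_same = round(truth.frac_same_direction * truth.n_overlap)

    categories: dict[str, str] = {}
    a_records, b_records = [], []
    for j, i in enumerate(shared):
        key = _protein_key(int(i))
        dir_a = "up" if rng.random() < 0.5 else "down"
        same = j < n_same
        dir_b = dir_a if same else ("down" if dir_a == "up" else "up")
        a_records.append(DiffRecord(key, dir_a, _log2fc(rng, dir_a)))
        b_records.append(DiffRecord(key, dir_b, _log2fc(rng, dir_b)))
        categories[key.uniprot] = ("same_up" if dir_a == "up" else "same_down") if same else "opposite"
    for i in a_only:
        key = _protein_key(int(i))
        d = "up" if rng.random() < 0.5 else "down"
        a_records.append(DiffRecord(key, d, _log2fc(rng, d)))
        categories[key.uniprot] = "a_only"
    for i in b_only:
        key = _protein_key(int(i))
        d = "up" if rng.random() < 0.5 else "down"
        b_records.append(DiffRecord(key, d, _log2fc(rng, d)))

    n_same_up = sum(1 for c in categories.values() if c == "same_up")
    answer = {
        "categories": categories,
        "summary": {
            "n_a": truth.n_a,
            "n_matched": truth.n_overlap,
            "n_same": n_same,
            "n_same_up": n_same_up,
            "n_same_down": n_same - n_same_up,
            "n_opposite": truth.n_overlap - n_same,
            "n_inconsistent_b": 0,
            "n_a_only": truth.n_a - truth.n_overlap,
        },
    }
    return (
        DiffTable(a_records, label="disease_a"),
        DiffTable(b_records, label="disease_b"),
        answer,
    )


def gen_category_scenario(
    n_same_up: int,
    n_same_down: int,
    n_opposite: int,
    n_inconsistent_b: int,
    n_a_only: int,
    seed: int = 0,
) -> tuple[DiffTable, dict[ProteinKey, DirectionCall], dict]:
    """Anchor table plus B-calls with an exact planted category composition.

    Unlike :func:`gen_disease_tables` this plants the B side directly as
    direction calls, so proteins whose prior-study evidence is inconsistent
    (no usable direction in B) can be planted too. Used to build scenario
    twins whose category counts are chosen up front.
    """
    for n in (n_same_up, n_same_down, n_opposite, n_inconsistent_b, n_a_only):
        _require(n >= 0, "category counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[DiffRecord] = []
    b_calls: dict[ProteinKey, DirectionCall] = {}
    categories: dict[str, str] = {}
    i = 0

    def add(category: str, dir_a: str, call: DirectionCall | None):
        nonlocal i
        key = _protein_key(i)
        i += 1
        records.append(DiffRecord(key, dir_a, _log2fc(rng, dir_a)))
        if call is not None:
            b_calls[key] = call
        categories[key.uniprot] = category

    for _ in range(n_same_up):
        add("same_up", "up", DirectionCall("increased", int(rng.integers(1, 9))))
    for _ in range(n_same_down):
        add("same_down", "down", DirectionCall("decreased", -int(rng.integers(1, 9))))
    for _ in range(n_opposite):
        if rng.random() < 0.5:
            add("opposite", "up", DirectionCall("decreased", -int(rng.integers(1, 9))))
        else:
            add("opposite", "down", DirectionCall("increased", int(rng.integers(1, 9))))
    for _ in range(n_inconsistent_b):
        add("inconsistent_b", "up" if rng.random() < 0.5 else "down", DirectionCall("inconsistent"))
    for _ in range(n_a_only):
        add("a_only", "up" if rng.random() < 0.5 else "down", None)

    order = rng.permutation(len(records))
    records = [records[j] for j in order]
    answer = {
        "categories": categories,
        "summary": {
            "n_a": len(records),
            "n_matched": n_same_up + n_same_down + n_opposite + n_inconsistent_b,
            "n_same": n_same_up + n_same_down,
            "n_same_up": n_same_up,
            "n_same_down": n_same_down,
            "n_opposite": n_opposite,
            "n_inconsistent_b": n_inconsistent_b,
            "n_a_only": n_a_only,
        },
    }
    return DiffTable(records, label="scenario_a"), b_calls, answer


def plant_reference_set(
    table: DiffTable,
    n_hits: int,
    size: int,
    name: str,
    seed: int = 0,
    categories: dict[str, str] | None = None,
    hit_categories: tuple[str, ...] | None = None,
) -> ReferenceSet:
    """Curated-list stand-in hitting exactly ``n_hits`` proteins of a table.

    ``n_hits`` keys are sampled from the table (optionally restricted to
    planted categories via ``categories``/``hit_categories``); the remaining
    ``size - n_hits`` members use a disjoint identifier namespace so the
    overlap is exact by construction.
    """
    _require(0 <= n_hits <= size, "n_hits must be <= size")
    pool = [
        r.key
        for r in table.records
        if hit_categories is None
        or (categories or {}).get(r.key.uniprot) in hit_categories
    ]
    _require(n_hits <= len(pool), f"table has only {len(pool)} eligible proteins for {n_hits} hits")
    rng = np.random.default_rng(seed)
    hits = [pool[j] for j in rng.choice(len(pool), size=n_hits, replace=False)]
    filler = [
        ProteinKey(uniprot=f"X{name[:3].upper()}{j:05d}", gene=f"{name[:4].upper()}F{j}")
        for j in range(size - n_hits)
    ]
    return ReferenceSet(name=name, keys=set(hits) | set(filler))


# ---------------------------------------------------------------------------
# multi-study signed report vectors


def gen_study_reports(
    n_proteins: int,
    report_count_range: tuple[int, int] = (1, 10),
    inconsistency_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[ProteinKey, list[int]], dict]:
    """Per-protein vectors of signed study reports with known planted calls.

    Consistent proteins get unanimous vectors; with probability
    ``inconsistency_rate`` a protein gets a balanced (or near-balanced)
    vector that the scoring rule must classify as inconsistent. The answer
    key maps each protein to its expected call and score.
    """
    lo, hi = report_count_range
    _require(1 <= lo <= hi <= 50, "report_count_range must lie within [1, 50]")
    _require(0 <= inconsistency_rate <= 1, "inconsistency_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    reports: dict[ProteinKey, list[int]] = {}
    answer: dict[str, dict] = {}
    for i in range(n_proteins):
        key = _protein_key(i)
        n = int(rng.integers(lo, hi + 1))
        if rng.random() < inconsistency_rate:
            n = max(n, 2)
            # balanced split: minority == 1 only for n in {2, 3} where the
            # majority is <= 2, so the forgiveness rule can never rescue it
            n_up = n // 2
            vec = [1] * n_up + [-1] * (n - n_up)
        else:
            sign = 1 if rng.random() < 0.5 else -1
            vec = [sign] * n
        rng.shuffle(vec)
        reports[key] = vec
        call = score_reports(vec)
        answer[key.uniprot] = {"call": call.call, "score": call.score}
    return reports, answer


# ---------------------------------------------------------------------------
# abundance matrix with planted modules


@dataclass(frozen=True)
class ModuleTruth:
    """Planted co-expression structure of a synthetic abundance matrix."""

    n_proteins: int = 200
    n_samples: int = 50
    module_sizes: tuple[int, ...] = (30, 30)
    within_module_cor: float = 0.8
    trait_module: int = 0
    trait_cor: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(sum(self.module_sizes) <= self.n_proteins, "module sizes exceed n_proteins")
        _require(abs(self.within_module_cor) <= 1, "|within_module_cor| must be <= 1")
        _require(abs(self.trait_cor) <= 1, "|trait_cor| must be <= 1")
        _require(0 <= self.trait_module < len(self.module_sizes), "trait_module out of range")
        _require(self.n_samples >= 4, "need n_samples >= 4 (correlation p undefined below df=2)")


def gen_expression(truth: ModuleTruth) -> tuple[AbundanceMatrix, np.ndarray, dict]:
    """Abundance matrix with planted modules and a module-driven trait.

    Each module m has a latent sample profile L_m ~ N(0,1); member proteins
    are sqrt(w)*L_m + sqrt(1-w)*eps with w = within_module_cor and
    eps ~ N(0, noise_sd^2), so with noise_sd = 1 the expected within-module
    correlation is exactly w. Remaining proteins are i.i.d. background
    noise. The trait is trait_cor * L_t + sqrt(1-trait_cor^2) * N(0,1) for
    the chosen trait module, giving expected trait correlation = trait_cor.
    """
    rng = np.random.default_rng(truth.seed)
    w = truth.within_module_cor
    values = np.empty((truth.n_proteins, truth.n_samples))
    labels = np.zeros(truth.n_proteins, dtype=int)
    latents = rng.standard_normal((len(truth.module_sizes), truth.n_samples))
    row = 0
    for m, size in enumerate(truth.module_sizes):
        eps = truth.noise_sd * rng.standard_normal((size, truth.n_samples))
        values[row : row + size] = np.sqrt(w) * latents[m] + np.sqrt(1 - w) * eps
        labels[row : row + size] = m + 1
        row += size
    values[row:] = rng.standard_normal((truth.n_proteins - row, truth.n_samples))

    r = truth.trait_cor
    trait = r * latents[truth.trait_module] + np.sqrt(1 - r**2) * rng.standard_normal(truth.n_samples)
    matrix = AbundanceMatrix(
        values,
        protein_keys=[f"P{i:05d}" for i in range(truth.n_proteins)],
        sample_ids=[f"S{j:03d}" for j in range(truth.n_samples)],
    )
    answer = {
        "labels": labels.tolist(),
        "trait_module": truth.trait_module + 1,  # 1-based planted module id
        "within_module_cor": w,
        "trait_cor": r,
    }
    return matrix, trait, answer


# ---------------------------------------------------------------------------
# stain images


@dataclass(frozen=True)
class StainImageTruth:
    """Planted composition of a flat-colour synthetic stain image."""

    width: int = 100
    height: int = 100
    positive_fraction: float = 0.25
    positive_color: tuple[int, int, int] = (120, 70, 20)  # DAB-like brown
    negative_color: tuple[int, int, int] = (70, 70, 160)  # hematoxylin-like blue
    seed: int = 0

    def __post_init__(self):
        _require(0 <= self.positive_fraction <= 1, "positive_fraction outside [0, 1]")
        _require(self.positive_color != self.negative_color, "stain colors must differ")
        _require(self.width > 0 and self.height > 0, "image must be non-empty")


def gen_stain_image(
    truth: StainImageTruth, roi_mask: np.ndarray | None = None, jitter_sd: float = 0.0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Flat-colour RGB image with an exact planted positive-pixel fraction.

    Exactly ``round(positive_fraction * n_roi)`` ROI pixels (scattered,
    seed-determined) get the positive colour; everything else the negative
    colour. Optional Gaussian RGB jitter is clipped to ±10 so the default
    colours never cross a classification boundary.
    """
    if roi_mask is None:
        roi_mask = np.ones((truth.height, truth.width), dtype=bool)
    roi_mask = np.asarray(roi_mask).astype(bool)
    _require(roi_mask.shape == (truth.height, truth.width), "ROI mask shape mismatch")
    _require(roi_mask.any(), "ROI must be non-empty")
    rng = np.random.default_rng(truth.seed)
    img = np.empty((truth.height, truth.width, 3), dtype=np.uint8)
    img[:] = truth.negative_color
    roi_idx = np.flatnonzero(roi_mask.ravel())
    n_pos = round(truth.positive_fraction * roi_idx.size)
    pos_idx = rng.choice(roi_idx, size=n_pos, replace=False)
    flat = img.reshape(-1, 3)
    flat[pos_idx] = truth.positive_color
    if jitter_sd > 0:
        noise = np.clip(rng.normal(0, jitter_sd, img.shape), -10, 10)
        img = np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)
    answer = {
        "n_roi": int(roi_idx.size),
        "n_positive": int(n_pos),
        "percent_positive": 100.0 * n_pos / roi_idx.size,
    }
    return img, roi_mask, answer


def write_png(array: np.ndarray, path) -> None:
    """Write an RGB or boolean-mask array as PNG."""
    from PIL import Image

    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(str(path))


def read_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path)))
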
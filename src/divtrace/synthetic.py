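"""Virtual premotor cohorts and stochastic dual-virus labelling.

`generate_cohort` realises a ground-truth premotor population from a
:class:`~divtrace.config.CordConfig`: every neuron gets an animal, a
region/segment/section, normalized transverse coordinates drawn within a
quadrant, a log-normal soma area, marker flags, and a connectivity class —
``A_only``/``B_only`` (contacts one injected motor pool) or ``both``
(a genuinely divergent neuron, drawn Bernoulli(d)).

`simulate_infection` then plays out the trans-synaptic labelling: each
neuron→pool connection transmits that pool's virus colour with probability
``e`` independently, except that in a divergent neuron the second virus (in
per-neuron random order) sees its efficiency reduced to ``e·(1-rho)`` when
the first has already succeeded (viral interference).  Only neurons that
receive at least one label appear in the output, which is exactly the table
a microscope count pipeline would produce — plus the ground-truth columns
``neuron_id``/``connectivity`` for validation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import CordConfig, VirusParams, REGIONS, QUADRANTS
from .errors import ConfigError

#: columns of an observed labelled-cell table
CELL_COLUMNS = [
    "animal_id", "region", "segment", "section_index",
    "x_norm", "y_norm", "labels", "soma_area",
    "glyt2_positive", "chat_positive", "lhx1_positive", "is_motoneuron",
]

#: extra ground-truth columns present on simulated tables
TRUTH_COLUMNS = ["neuron_id", "connectivity"]

_QUADRANT_SIGN = {"DI": (1, 1), "DC": (-1, 1), "VI": (1, -1), "VC": (-1, -1)}


def _allocate_animals(n: int, n_animals: int) -> np.ndarray:
    """Even split of n neurons over animals, remainder to the first ones."""
    base, extra = divmod(n, n_animals)
    counts = [base + (1 if i < extra else 0) for i in range(n_animals)]
    return np.repeat(np.arange(1, n_animals + 1), counts)


def generate_cohort(config: CordConfig,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a ground-truth premotor cohort.

    Parameters
    ----------
    config : CordConfig
        Population description; per region, ``n_premotor`` neurons are
        generated for each of ``config.n_animals`` animals.
    seed : int, optional
        Overrides ``config.seed``.  A fixed seed gives a byte-identical
        table.

    Returns
    -------
    pandas.DataFrame
        One row per neuron with ground-truth connectivity.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 1
    for region in REGIONS:  # fixed iteration order for determinism
        if region not in config.regions:
            continue
        spec = config.regions[region]
        n = spec.n_premotor * config.n_animals
        if n == 0:
            continue
        animal = _allocate_animals(n, config.n_animals)

        u = rng.random(n)
        connectivity = np.where(
            u < spec.divergent_fraction, "both",
            np.where(rng.random(n) < spec.ab_split, "A_only", "B_only"))

        probs = np.array([spec.quadrant_probs[q] for q in QUADRANTS], float)
        quad_idx = rng.choice(len(QUADRANTS), size=n, p=probs / probs.sum())
        signs = np.array([_QUADRANT_SIGN[q] for q in QUADRANTS], float)
        # magnitudes drawn in (0, 1] so a degenerate quadrant stays strict
        x = signs[quad_idx, 0] * (1.0 - rng.random(n))
        y = signs[quad_idx, 1] * (1.0 - rng.random(n))

        section = rng.integers(0, spec.n_sections, size=n)
        seg_labels = np.asarray(spec.segments, dtype=object)
        segment = seg_labels[section * len(seg_labels) // spec.n_sections]

        soma = rng.lognormal(spec.soma_logmean, spec.soma_logsd, size=n)
        glyt2 = rng.random(n) < spec.inhibitory_fraction
        chat = rng.random(n) < spec.cholinergic_fraction

        frames.append(pd.DataFrame({
            "neuron_id": np.arange(next_id, next_id + n),
            "animal_id": animal,
            "region": region,
            "segment": segment,
            "section_index": section,
            "x_norm": x,
            "y_norm": y,
            "connectivity": connectivity,
            "soma_area": soma,
            "glyt2_positive": glyt2,
            "chat_positive": chat,
            "is_motoneuron": False,
        }))
        next_id += n

    if config.include_motoneurons:
        frames.append(_motoneuron_rows(config, rng, next_id))

    if not frames:
        return _empty_cohort()
    out = pd.concat(frames, ignore_index=True)
    return out


def _motoneuron_rows(config: CordConfig, rng: np.random.Generator,
                     next_id: int) -> pd.DataFrame:
    """Primary-infected motoneuron rows for table realism.

    MNs sit in the ventral ipsilateral grey matter of the injected region
    (lumbar when present) and are connected to exactly one pool; they never
    enter premotor divergence denominators.
    """
    region = "lumbar" if "lumbar" in config.regions else next(iter(config.regions))
    spec = config.regions[region]
    n = 2 * config.n_motoneurons
    animal = _allocate_animals(n, config.n_animals)
    section = rng.integers(0, spec.n_sections, size=n)
    seg_labels = np.asarray(spec.segments, dtype=object)
    return pd.DataFrame({
        "neuron_id": np.arange(next_id, next_id + n),
        "animal_id": animal,
        "region": region,
        "segment": seg_labels[section * len(seg_labels) // spec.n_sections],
        "section_index": section,
        "x_norm": 0.3 + 0.4 * rng.random(n),
        "y_norm": -(0.4 + 0.5 * rng.random(n)),
        "connectivity": np.where(np.arange(n) % 2 == 0, "A_only", "B_only"),
        "soma_area": rng.lognormal(spec.soma_logmean + 0.7,
                                   spec.soma_logsd, size=n),
        "glyt2_positive": False,
        "chat_positive": True,  # motoneurons are cholinergic
        "is_motoneuron": True,
    })


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "neuron_id", "animal_id", "region", "segment", "section_index",
        "x_norm", "y_norm", "connectivity", "soma_area",
        "glyt2_positive", "chat_positive", "is_motoneuron"])


def simulate_infection(neurons: pd.DataFrame, virus: VirusParams,
                       seed: int = 0,
                       spillover_prob: float = 0.0) -> pd.DataFrame:
    """Simulate dual-virus trans-synaptic labelling of a cohort.

    Each connection to pool A (B) transmits colour A (B) with probability
    ``virus.efficiency``; in divergent neurons the two viruses are played in
    per-neuron random order and a success of the first multiplies the
    second's efficiency by ``1 - virus.interference``.  Motoneuron rows are
    primary infection targets and receive their pool's colour with
    probability 1.

    Parameters
    ----------
    neurons : DataFrame
        Output of :func:`generate_cohort` (requires ``connectivity``).
    virus : VirusParams
    seed : int
        Seeds all transmission randomness.
    spillover_prob : float
        Probability that a labelled cell is (wrongly) recorded again on an
        adjacent section — the counting artefact that 1-in-k section
        subsampling is designed to avoid.

    Returns
    -------
    DataFrame
        Labelled cells only (>= 1 colour), columns ``CELL_COLUMNS`` +
        ``TRUTH_COLUMNS``.
    """
    if not (0.0 <= spillover_prob <= 1.0):
        raise ConfigError(
            f"spillover_prob must lie in [0, 1], got {spillover_prob}")
    rng = np.random.default_rng(seed)
    n = len(neurons)
    if n == 0:
        return _empty_cells()

    conn = neurons["connectivity"].to_numpy()
    is_mn = neurons["is_motoneuron"].to_numpy().astype(bool) \
        if "is_motoneuron" in neurons else np.zeros(n, bool)
    e, rho = virus.efficiency, virus.interference

    both = (conn == "both") & ~is_mn
    a_only = (conn == "A_only") & ~is_mn
    b_only = (conn == "B_only") & ~is_mn

    # divergent neurons: random virus order, interference on the second
    b_first = rng.integers(0, 2, size=n).astype(bool)
    u1, u2, us = rng.random(n), rng.random(n), rng.random(n)
    first_ok = u1 < e
    second_ok = u2 < np.where(first_ok, e * (1.0 - rho), e)
    lab_a = both & np.where(b_first, second_ok, first_ok)
    lab_b = both & np.where(b_first, first_ok, second_ok)

    # single-pool neurons: one independent Bernoulli(e) connection
    lab_a |= a_only & (us < e)
    lab_b |= b_only & (us < e)

    # motoneurons: primary (injection-site) infection, certain
    lab_a |= is_mn & (conn == "A_only")
    lab_b |= is_mn & (conn == "B_only")

    labelled = lab_a | lab_b
    ca, cb = virus.colours
    labels = np.where(
        lab_a & lab_b, f"{ca}+{cb}", np.where(lab_a, ca, cb))

    cells = pd.DataFrame({
        "animal_id": neurons["animal_id"].to_numpy(),
        "region": neurons["region"].to_numpy(),
        "segment": neurons["segment"].to_numpy(),
        "section_index": neurons["section_index"].to_numpy(),
        "x_norm": neurons["x_norm"].to_numpy(),
        "y_norm": neurons["y_norm"].to_numpy(),
        "labels": labels,
        "soma_area": neurons["soma_area"].to_numpy(),
        "glyt2_positive": neurons["glyt2_positive"].to_numpy(),
        "chat_positive": neurons["chat_positive"].to_numpy(),
        "lhx1_positive": pd.array([pd.NA] * n, dtype="boolean"),
        "is_motoneuron": is_mn,
        "neuron_id": neurons["neuron_id"].to_numpy(),
        "connectivity": conn,
    })[labelled].reset_index(drop=True)

    if spillover_prob > 0.0 and len(cells):
        dup = cells[rng.random(len(cells)) < spillover_prob].copy()
        step = np.where(rng.random(len(dup)) < 0.5, -1, 1)
        dup["section_index"] = np.maximum(
            dup["section_index"].to_numpy() + step, 0)
        cells = pd.concat([cells, dup], ignore_index=True)

    return cells


def _empty_cells() -> pd.DataFrame:
    df = pd.DataFrame(columns=CELL_COLUMNS + TRUTH_COLUMNS)
    return df.astype({"lhx1_positive": "boolean"}, errors="ignore")
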
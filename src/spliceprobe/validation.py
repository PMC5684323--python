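"""Simulation studies validating each pipeline stage against known truth.

Every function generates its own synthetic inputs, runs the package's
public interfaces and measures recovery, error or calibration.  They are
used both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from click.testing import CliRunner

from . import assays, cli, displacement, events, psi, silac, simulate


def _truth_key(g: dict) -> tuple:
    return (
        g["gene_id"],
        g["category"],
        min(g["flank_left"], g["flank_right"]),
        max(g["flank_left"], g["flank_right"]),
        tuple(tuple(iv) for iv in g["alt1"]),
        tuple(tuple(iv) for iv in g["alt2"]),
    )


def _event_key(ev: events.AltEvent) -> tuple:
    left, right = ev.region
    return (ev.gene_id, ev.category, left, right, ev.alt1, ev.alt2)


def event_catalog_roundtrip(seed: int = 0, events_per_category: int = 2) -> dict:
    """Generate genes covering all six categories, run the catalog builder
    through the CLI, and compare with the generator's truth table."""
    models, truth = simulate.gen_transcriptome(seed, events_per_category)
    runner = CliRunner()
    with tempfile.TemporaryDirectory() as tmp:
        gtf = str(Path(tmp) / "genes.gtf")
        out = str(Path(tmp) / "events.json")
        events.write_gtf(models, gtf)
        result = runner.invoke(
            cli.main,
            ["build-events", "--gtf", gtf, "--read-len", "50", "--min-overhang", "1", "--out", out],
            catch_exceptions=False,
        )
        if result.exit_code != 0:
            raise RuntimeError(f"build-events failed: {result.output}")
        catalog = [ev for ev, _ in events.read_events_json(out)]
    expected = {_truth_key(g) for g in truth["genes"]}
    found = {_event_key(ev) for ev in catalog}
    recovered = len(expected & found) / len(expected)
    spurious = len(found - expected)
    return {
        "recovered_fraction": recovered,
        "spurious": spurious,
        "n_expected": len(expected),
    }


def _one_cassette_fixture(seed: int):
    models, truth = simulate.gen_transcriptome(
        seed, {"CASSETTE": 1}, include_ese2_gene=False
    )
    gene = truth["genes"][0]["gene_id"]
    catalog = events.build_catalog(models)
    (event,) = [e for e in catalog if e.category == "CASSETTE"]
    regions = events.compute_unique_regions(event)
    return models, gene, event, regions


def _estimate_psi(models, gene, event, regions, psi_true, depth, seed, sample_id="S1"):
    alignments, _ = simulate.gen_reads(
        models, {gene: psi_true}, depth, seed=seed, sample_id=sample_id
    )
    counts = psi.quantify_event(event, regions, alignments, sample_id)
    return psi.compute_psi(counts)


def psi_recovery(
    seed: int = 0,
    psis: tuple[float, ...] = (0.1, 0.5, 0.9),
    depth: int = 2000,
    replicates: int = 5,
) -> dict:
    """Mean absolute PSI estimation error per simulated level."""
    models, gene, event, regions = _one_cassette_fixture(seed)
    rng = np.random.default_rng(seed)
    mae = {}
    for level in psis:
        errors = []
        for _ in range(replicates):
            est = _estimate_psi(
                models, gene, event, regions, level, depth, int(rng.integers(2**31))
            )
            errors.append(abs(est - level))
        mae[level] = float(np.mean(errors))
    return {"mae": mae, "max_mae": max(mae.values())}


def delta_psi_power(
    seed: int = 0,
    n_runs: int = 100,
    psi_treated: float = 0.7,
    psi_control: float = 0.2,
    depth: int = 2000,
    replicates: int = 5,
    threshold: float = psi.DELTA_PSI_THRESHOLD,
) -> dict:
    """Fraction of simulation runs in which a true dPSI separation is
    flagged at the given threshold."""
    models, gene, event, regions = _one_cassette_fixture(seed)
    rng = np.random.default_rng(seed + 1)
    flagged = 0
    for _ in range(n_runs):
        psis = {}
        for condition, level in (("treated", psi_treated), ("control", psi_control)):
            vals = [
                _estimate_psi(
                    models, gene, event, regions, level, depth,
                    int(rng.integers(2**31)), sample_id=f"{condition}{r}"
                )
                for r in range(replicates)
            ]
            psis[condition] = psi.PsiRecord(event.event_id, condition, tuple(vals))
        _, flag = psi.delta_psi(psis["treated"], psis["control"], threshold)
        flagged += flag
    return {"flag_rate": flagged / n_runs, "n_runs": n_runs}


def density_filter_agreement(seed: int = 0, n_events: int = 300, n_samples: int = 4) -> dict:
    """Exact agreement of the density filter with a brute-force scan."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_events):
        for s in range(n_samples):
            # mass around the 0.003 threshold to exercise the boundary
            c1 = float(rng.choice([0.0, 0.0029, 0.003, 0.0031]) + rng.random() * 0.002 * rng.integers(0, 2))
            c2 = float(rng.choice([0.0, 0.001, 0.0029, 0.004]))
            rows.append({"event_id": f"e{i:04d}", "sample_id": f"S{s}", "c1": c1, "c2": c2})
    table = pd.DataFrame(rows)
    fast = set(psi.filter_events(table))
    brute = set()
    for r in table.itertuples():
        if r.c1 >= 0.003 or r.c2 >= 0.003:
            brute.add(r.event_id)
    return {"agreement": float(fast == brute), "n_events": n_events}


def silac_performance(seed: int = 0, n_runs: int = 50, **gen_kwargs) -> dict:
    """Sensitivity and observed FDR of the SILAC pipeline on spiked tables,
    plus exact agreement of the filter chain with a brute-force filter."""
    rng = np.random.default_rng(seed)
    sens, fdr, filter_ok = [], [], True
    for _ in range(n_runs):
        table, truth = simulate.gen_silac(int(rng.integers(2**31)), **gen_kwargs)
        res = silac.silac_enrich(table, truth["swapped_samples"])
        called = set(res.index[res["enriched"]])
        enriched = set(truth["enriched"])
        sens.append(len(called & enriched) / len(enriched))
        fdr.append(len(called - enriched) / max(1, len(called)))
        filter_ok &= _filter_matches_bruteforce(table)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "filter_agreement": float(filter_ok),
        "n_runs": n_runs,
    }


def _filter_matches_bruteforce(table: pd.DataFrame) -> bool:
    fast = silac.filter_protein_table(table)
    ratio_cols = silac.ratio_columns(table)
    surviving = []
    for idx, row in table.iterrows():
        detected = sum(not pd.isna(row[c]) for c in ratio_cols)
        if row["n_quant_peptides"] >= 2 and row["score"] > 31 and detected >= 7:
            surviving.append(idx)
    best: dict[str, int] = {}
    for idx in surviving:
        row = table.loc[idx]
        pid = row["protein_id"]
        if pid not in best:
            best[pid] = idx
        else:
            cur = table.loc[best[pid]]
            if (row["intensity"], -row["band_id"], -idx) > (
                cur["intensity"], -cur["band_id"], -best[pid]
            ):
                best[pid] = idx
    return sorted(best.values()) == sorted(fast.index)


def minp_exhaustive_agreement(seed: int = 0) -> dict:
    """Step-down minP on a tiny two-level design vs. exhaustive enumeration
    computed by independent brute-force loops."""
    rng = np.random.default_rng(seed)
    n_rep = 2
    samples = [f"s{i}" for i in range(2 * n_rep)]
    conc = (0.0, 0.0, 10.0, 10.0)
    design = displacement.DoseDesign(tuple(samples), conc)
    matrix = pd.DataFrame(
        rng.normal(0, 1, (3, 4)), index=["pA", "pB", "pC"], columns=samples
    )
    matrix.iloc[0, :2] += 2.0  # one displaced-looking protein
    res = displacement.permute_and_minp(matrix, design, exhaustive=True)

    # brute force: enumerate the 6 distinct label assignments directly
    from itertools import combinations

    values = matrix.to_numpy()
    assignments = []
    for low in combinations(range(4), 2):
        lab = np.array([0 if i in low else 1 for i in range(4)])
        assignments.append(lab)

    def stat(lab: np.ndarray) -> np.ndarray:
        masks = [lab == 0, lab == 1]
        means = [values[:, m].mean(axis=1) for m in masks]
        s2 = np.array(
            [
                sum(((values[j, m] - values[j, m].mean()) ** 2).sum() for m in masks)
                / (4 - 2)
                for j in range(3)
            ]
        )
        d0, s0, spost = displacement.squeeze_variances(s2, np.full(3, 2.0))
        se = np.sqrt(spost * (1 / 2 + 1 / 2))
        return (means[0] - means[1]) / se

    obs = stat(np.array([0, 0, 1, 1]))
    null = np.column_stack([stat(lab) for lab in assignments])
    n_assign = null.shape[1]
    raw = (null >= obs[:, None]).sum(axis=1)
    colp = np.zeros_like(null, dtype=int)
    for j in range(3):
        for b in range(n_assign):
            colp[j, b] = int((null[j] >= null[j, b]).sum())
    order = np.lexsort((np.arange(3), -obs, raw))
    adj = np.zeros(3)
    prev = 0.0
    for rank, j in enumerate(order):
        hits = 0
        for b in range(n_assign):
            q = min(colp[k, b] for k in order[rank:])
            hits += q <= raw[j]
        adj[j] = max(prev, hits / n_assign)
        prev = adj[j]
    max_diff = float(
        max(
            np.abs(res["p_minp"].to_numpy() - raw / n_assign).max(),
            np.abs(res["p_adj"].to_numpy() - adj).max(),
        )
    )
    return {"max_abs_diff": max_diff, "n_assignments": n_assign}


def displacement_type1(
    seed: int = 0, n_seeds: int = 20, n_permutations: int = 1000, **gen_kwargs
) -> dict:
    """Per-protein binder-call rate on pure-null dose-response matrices."""
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_seeds):
        matrix, design_df, _ = simulate.gen_dose_response(
            int(rng.integers(2**31)), n_displaced=0, **gen_kwargs
        )
        design = displacement.DoseDesign.from_table(design_df)
        res = displacement.permute_and_minp(
            matrix, design, n_permutations=n_permutations, seed=int(rng.integers(2**31))
        )
        tested = int(res["tested"].sum())
        rates.append(int(res["binder"].sum()) / max(1, tested))
    rates = np.array(rates)
    mc_sd = float(rates.std(ddof=1) / math.sqrt(len(rates))) if len(rates) > 1 else 0.0
    return {
        "call_rate": float(rates.mean()),
        "mc_sd": mc_sd,
        "n_seeds": n_seeds,
    }


def displacement_power(
    seed: int = 0,
    n_seeds: int = 20,
    n_permutations: int = 1000,
    n_displaced: int = 10,
    sd: float = 0.25,
    **gen_kwargs,
) -> dict:
    """Sensitivity for spiked displaced proteins (per-level drop 2*sd)."""
    rng = np.random.default_rng(seed)
    sens = []
    for _ in range(n_seeds):
        matrix, design_df, truth = simulate.gen_dose_response(
            int(rng.integers(2**31)),
            n_displaced=n_displaced,
            drop_per_level=2 * sd,
            sd=sd,
            **gen_kwargs,
        )
        design = displacement.DoseDesign.from_table(design_df)
        res = displacement.permute_and_minp(
            matrix, design, n_permutations=n_permutations, seed=int(rng.integers(2**31))
        )
        called = set(res.index[res["binder"]])
        sens.append(len(called & set(truth["displaced"])) / n_displaced)
    return {"sensitivity": float(np.mean(sens)), "n_seeds": n_seeds}


def closed_form_checks() -> dict:
    """Hand-computed toy values for every closed-form operation."""
    errors = [
        abs(assays.ddct_fold(20, 18, 22, 19) - 2.0 ** (-((20 - 18) - (22 - 19)))),
        abs(assays.ddct_fold(5, 5, 5, 5) - 1.0),
        abs(psi.compute_rpkm(1000, 2000, 10_000_000) - 50.0),
        abs(
            psi.compute_psi(psi.EventCounts("e", "s", 10, 5, 0.05, 0.1)) - (0.05 / 0.15)
        ),
        abs(
            assays.spr_percent_binding(
                assays.SprMeasurement(50.0, 400.0, 8000.0, 1000.0)
            )
            - 100.0 * 50.0 / (1000.0 * 400.0 / 8000.0)
        ),
        abs(
            assays.abundance_from_ct(assays.QpcrRecord("s", "t", 10.0, 2.0))
            - 2.0 ** -10
        ),
    ]
    return {"max_abs_error": float(max(errors))}


def cli_determinism(seed: int = 17) -> dict:
    """Byte-identity of seeded CLI outputs across repeated invocations."""
    runner = CliRunner()
    identical = True
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)

        def _run(args):
            result = runner.invoke(cli.main, args, catch_exceptions=False)
            if result.exit_code != 0:
                raise RuntimeError(f"CLI failed: {args}\n{result.output}")

        for rep in ("a", "b"):
            _run(
                [
                    "simulate", "transcriptome", "--seed", str(seed),
                    "--gtf-out", str(tmp / f"t_{rep}.gtf"),
                    "--truth-out", str(tmp / f"t_{rep}.json"),
                ]
            )
            _run(
                [
                    "simulate", "reads", "--seed", str(seed),
                    "--gtf", str(tmp / f"t_{rep}.gtf"), "--psi", "0.5",
                    "--depth", "200", "--sam-out", str(tmp / f"r_{rep}.sam"),
                ]
            )
            _run(
                [
                    "simulate", "dose-response", "--seed", str(seed),
                    "--n-proteins", "40", "--n-displaced", "2",
                    "--matrix-out", str(tmp / f"m_{rep}.tsv"),
                    "--design-out", str(tmp / f"d_{rep}.tsv"),
                    "--truth-out", str(tmp / f"dr_{rep}.json"),
                ]
            )
            _run(
                [
                    "displace-test", "--matrix", str(tmp / f"m_{rep}.tsv"),
                    "--design", str(tmp / f"d_{rep}.tsv"),
                    "--perms", "100", "--seed", str(seed),
                    "--out", str(tmp / f"res_{rep}.tsv"),
                ]
            )
        for stem in ("t_{}.gtf", "t_{}.json", "r_{}.sam", "m_{}.tsv", "res_{}.tsv"):
            a = (tmp / stem.format("a")).read_bytes()
            b = (tmp / stem.format("b")).read_bytes()
            identical &= a == b
    return {"identical": float(identical)}
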
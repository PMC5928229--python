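"""Independent brute-force ΔΔCt recomputation used as a test oracle.

Deliberately written with plain dict/loop bookkeeping (no shared code with
the package's pandas pipeline) so that agreement between the two is a real
cross-check of the quantification chain.
"""

from __future__ import annotations

from collections import defaultdict

DNA_REF = "DNA_REF"


def brute_force_fold_changes(rows):
    """Fold changes vs the pool reference, straight from raw Cq rows.

    ``rows`` is an iterable of dicts with keys sample_id, mouse_id, pool_id,
    compartment, probe, replicate, cq, censored.  Returns
    ``{(sample_id, probe): fold_change}`` for uncensored tumor measurements.
    """
    reps = defaultdict(list)
    meta = {}
    for r in rows:
        if not r["censored"]:
            reps[(r["sample_id"], r["probe"])].append(r["cq"])
        meta[r["sample_id"]] = (r["pool_id"], r["compartment"], r["mouse_id"])

    collapsed = {k: sum(v) / len(v) for k, v in reps.items()}

    delta = {}
    for (sample, probe), cq in collapsed.items():
        if probe == DNA_REF:
            continue
        delta[(sample, probe)] = cq - collapsed[(sample, DNA_REF)]

    ref_delta = {}
    for (sample, probe), d in delta.items():
        pool, compartment, _ = meta[sample]
        if compartment == "reference":
            ref_delta[(pool, probe)] = d

    out = {}
    for (sample, probe), d in delta.items():
        pool, compartment, _ = meta[sample]
        out[(sample, probe)] = 2.0 ** -(d - ref_delta[(pool, probe)])
    return out


def brute_force_enrichment(rows, min_pairs=3):
    """Per-ORF mean lung-vs-MFP ratio and pair count from raw Cq rows.

    Pairs require an uncensored lung and MFP fold change from the same mouse
    (the detected-only pair policy).
    """
    fc = brute_force_fold_changes(rows)
    meta = {}
    for r in rows:
        meta[r["sample_id"]] = (r["pool_id"], r["compartment"], r["mouse_id"])

    by_mouse = defaultdict(dict)
    for (sample, probe), value in fc.items():
        pool, compartment, mouse = meta[sample]
        if compartment in ("mfp", "lung"):
            by_mouse[(mouse, probe)][compartment] = value

    pairs = defaultdict(list)
    for (mouse, probe), comps in by_mouse.items():
        if "mfp" in comps and "lung" in comps:
            pairs[probe].append(comps["lung"] / comps["mfp"])

    return {
        probe: {
            "n_pairs": len(vals),
            "score": sum(vals) / len(vals),
            "included": len(vals) >= min_pairs,
        }
        for probe, vals in pairs.items()
    }
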
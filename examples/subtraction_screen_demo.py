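"""End-to-end demo: recover planted W-specific sequence from read coverage.

Simulates a small ZW cohort (3 females + 3 males at 12x plus a male pool
of 8), maps every library to both per-sex references with the built-in
ungapped mapper, and runs the subtraction screen: same-sex common regions,
strict zero-coverage subtraction of opposite-sex reads, the pool filter,
and composition filters.  Prints the stage attrition and compares the
final candidates with the ground truth.  Takes ~20 s.
"""

from sexscreen.workflow import RunConfig, run_workflow

cfg = RunConfig.from_dict(
    {
        "seed": 7,
        "system": "ZW",
        "genome": {
            "autosome_length": 40_000,
            "sex_shared_length": 6_000,
            "unique_lengths": [800, 1_200],
            "n_traps": 4,
            "trap_length": 300,
        },
        "cohort": {"n_females": 3, "n_males": 3, "pool_size": 8},
        "reads": {"depth": 12, "pool_depth": 40},
        "markers": {"n_test_individuals": 6},
    }
)
result = run_workflow(cfg)
print(result.report)
print(
    "Every number above is recomputed from the reads; the Jaccard line"
    " compares the final intervals with the planted W-unique insertions,"
    " and 'trap loci retained' counts autosomal pseudo-markers that"
    " survived (the pool filter should leave zero)."
)
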
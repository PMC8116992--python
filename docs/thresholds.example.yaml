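# Example QC threshold configuration for `ngsqr stats dist` / `ngsqr stats status`.
#
# No thresholds ship enabled by default: pass/fail cut-offs are laboratory
# policy (assay-, panel- and specimen-dependent), not package policy.  The
# values below are illustrative starting points only — set your own.
#
# direction: ge  -> value must be >= threshold to pass
#            le  -> value must be <= threshold to pass
thresholds:
  - metric: sequencing.pct_q30        # percent of bases >= Q30, run level
    direction: ge
    value: 75
  - metric: processing.mean_coverage  # mean on-target coverage, fold
    direction: ge
    value: 500
  - metric: processing.on_target_rate # percent of reads on target
    direction: ge
    value: 50
  - metric: sequencing.error_rate     # run error rate, percent
    direction: le
    value: 2.0
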
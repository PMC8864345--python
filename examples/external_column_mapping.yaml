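# Column-name adapter for externally shared study-level effect tables.
# Keys are the external CSV's column names, values are this package's
# schema names (phenomenon_id, study_label, estimate,
# variance | standard_error, direction_flip).
#
# Example layout matching commonly shared meta-analysis exports:
effect: phenomenon_id
study: study_label
d: estimate
se: standard_error
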
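The packaged S-value matrix (s_matrix_lu177_illustrative.csv), reference
masses, sphere absorbed fractions and tissue weights are ILLUSTRATIVE,
synthetic configuration, not authoritative phantom data.

They were constructed from the Lu-177 electron mean energy per decay
(~0.085 Gy*g per MBq*h) and simple absorbed-fraction reasoning so that the
pipeline runs offline and produces doses of realistic magnitude for a
bone-seeking tracer (marrow dominated by skeletal cross-irradiation,
low kidney doses). They are NOT the kernels of any published dosimetry
engine. For clinical or comparative work, replace them with S-values
exported from a validated phantom code via the documented CSV interface.
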
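"""Judge a fitted model against the standard fit-index reference bands.

CMIN/DF (1-3), CFI/TLI/IFI (> 0.90) and SRMR (< 0.08) compare the model to
the data and to an independence baseline; composite reliability CR (> 0.7)
and average variance extracted AVE (> 0.5) summarize construct quality from
the standardized loadings alone.
"""

from semfi import INDICATORS, fit_cfa, fit_index_report, verdicts, zscore_normalize
from semfi.cfa import build_default_model
from semfi.synthetic import SyntheticSpec, generate

table = generate(SyntheticSpec.homogeneous(seed=42))
ztable, _ = zscore_normalize(table, INDICATORS)
fit = fit_cfa(build_default_model(), ztable[list(INDICATORS)])
report = fit_index_report(fit)
print(report.to_frame().to_string(index=False))

# the verdict function can also judge an externally reported battery:
print("\nexternally reported battery (2.844, 0.970, 0.911, 0.971, 0.0536):")
print(verdicts(2.844, 0.970, 0.911, 0.971, 0.0536))
# every index inside its band -> the model structure is consistent with the
# observed covariances.
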
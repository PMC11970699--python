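"""Check that the estimator recovers known rates from simulated camp tables.

Camp tables are drawn from the binomial person-time model at known true
rates; the full pipeline is rerun on each and compared with the truth.
"""

import campmort as cm
from campmort.synthetic import SimulationSpec

config = cm.StudyConfig()
spec = SimulationSpec(true_b=174.0, true_m=370.0, n_camps=17, seed=12345)

df, summary = cm.recovery_experiment(spec, replicates=50, config=config)

print(f"True rates: b = {spec.true_b}, m = {spec.true_m} per million person-days")
print(f"True excess toll: {summary['true_excess']:,.0f} deaths")
print()
print(f"Over {summary['replicates']} simulated camp tables:")
print(f"  bias(b)  = {summary['bias_b']:+8.2f}   RMSE(b) = {summary['rmse_b']:.2f}")
print(f"  bias(m)  = {summary['bias_m']:+8.2f}   RMSE(m) = {summary['rmse_m']:.2f}")
print(f"  bias(excess) = {summary['bias_excess']:+,.0f}")
print(f"  CI coverage  = {summary['ci_coverage']:.2f}")
print()
print("Small bias and RMSE show the robust fit recovers the generating")
print("rates. Note the CI coverage: the interval uses the raw variance of")
print("the leave-one-out totals, which understates jackknife sampling")
print("variance on clean model-generated data (see docs/methods.md).")
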
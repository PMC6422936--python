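# Preset calibration: achieved vs target

Pipeline outputs of the packaged presets (500 cells x 3 replicates,
300 min at 2.5-min frames) against the per-condition summary
statistics they were calibrated to. Achieved values are means over
replicates with seeds [1, 2, 3]; targets are published means with
their SDs. Regenerate with `python scripts/calibrate_presets.py`.

| condition | metric | target (mean ± SD) | achieved |
|---|---|---|---|
| unstimulated | endpoint_percent_fmlp | 9.157 ± 3.599 | 10.229 |
| unstimulated | endpoint_percent_ltb4 | 4.811 ± 3.822 | 4.921 |
| unstimulated | rate_fmlp | 4.604 ± 2.869 | 5.262 |
| unstimulated | rate_ltb4 | 1.525 ± 1.552 | 2.374 |
| unstimulated | velocity_fmlp | 10.51 ± 3.91 | 10.978 |
| unstimulated | velocity_ltb4 | 9.45 ± 3.61 | 9.083 |
| unstimulated | spontaneous_percent | 10.0 ± 5.0 | 9.904 |
| superlow_lps | endpoint_percent_fmlp | 16.06 ± 3.349 | 15.921 |
| superlow_lps | endpoint_percent_ltb4 | 18.52 ± 6.944 | 19.536 |
| superlow_lps | rate_fmlp | 9.056 ± 4.209 | 9.162 |
| superlow_lps | rate_ltb4 | 10.73 ± 0.3047 | 11.547 |
| superlow_lps | velocity_fmlp | 8.54 ± 2.87 | 8.754 |
| superlow_lps | velocity_ltb4 | 9.58 ± 3.36 | 9.484 |
| superlow_lps | spontaneous_percent | 30.0 ± 5.0 | 30.354 |
| high_lps | endpoint_percent_fmlp | 19.4 ± 3.07 | 21.045 |
| high_lps | endpoint_percent_ltb4 | 1.894 ± 0.6725 | 1.944 |
| high_lps | rate_fmlp | 14.56 ± 1.388 | 15.782 |
| high_lps | rate_ltb4 | 0.695 ± 0.6533 | 1.459 |
| high_lps | velocity_fmlp | 10.23 ± 3.57 | 10.498 |
| high_lps | velocity_ltb4 | 8.66 ± 3.14 | 7.925 |
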
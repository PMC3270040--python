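panel	genes	carriers	n_total	mean_exam_age	note
unselected_gsk	APP;PSEN1;PSEN2	376	12481	51.7	rare non-synonymous variant carriers in an unselected population panel
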
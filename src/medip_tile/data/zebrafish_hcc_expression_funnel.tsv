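stage	count
expression_significant	194
with_promoter_cgi	68
on_array	49
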
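# Dialect for the archived catalogue export (dotted column headers).
column.input_name = Input.Taxon
column.status = Status
column.accepted_name = Output.Taxon
column.family = Family
column.order = Order
column.tpl_comparison = PL.comparison
status.accepted = accepted
status.valid = accepted
status.synonym = synonym
status.invalid = synonym
status.unresolved = unresolved
status.blank = unresolved
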
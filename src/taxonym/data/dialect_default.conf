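# Default backbone dialect: column mapping and status vocabulary.
column.input_name = Input_Taxon
column.status = Status
column.accepted_name = Output_Taxon
column.family = Family
column.order = Order
column.tpl_comparison = TPL_Comparison
status.accepted = accepted
status.synonym = synonym
status.unresolved = unresolved
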
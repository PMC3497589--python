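# Bootstrap attribute dictionary: defines, in its own formalism, the
# attribute tags used to write dictionaries.  Parsing this file yields a
# dictionary against which this file itself validates cleanly.

data_on_this_dictionary
_dictionary_name ddl_bootstrap.dic

data_name
_name     '_name'
_category dictionary_definition
_type     char
_list     no
_definition
;The tag being defined by this data block.  Must begin with an
underscore character.
;

data_category
_name     '_category'
_category dictionary_definition
_type     char
_list     no
_definition
;Identifier grouping related definitions.
;

data_type
_name     '_type'
_category dictionary_definition
_type     char
_list     no
loop_
  _enumeration
  numb
  char
_definition
;Base data type of the defined tag: 'numb' for values that must lex as
numbers, 'char' for free character strings.
;

data_units
_name     '_units'
_category dictionary_definition
_type     char
_list     no
_definition
;Code for the preferred unit in which values of the defined tag are
expressed.  Declarative: values are asserted, never converted.
;

data_enumeration
_name     '_enumeration'
_category dictionary_definition
_type     char
_list     both
_definition
;An allowed value of the defined tag; looped when several values are
permitted.  Mutually exclusive with _enumeration_range.
;

data_enumeration_range
_name     '_enumeration_range'
_category dictionary_definition
_type     char
_list     no
_definition
;Closed numeric range for the defined tag, written 'min:max'; either
bound may be omitted.  Requires _type numb.
;

data_list
_name     '_list'
_category dictionary_definition
_type     char
_list     no
loop_
  _enumeration
  yes
  no
  both
_definition
;Whether the defined tag must appear in a loop ('yes'), must not
('no'), or may appear either way ('both').
;

data_definition
_name     '_definition'
_category dictionary_definition
_type     char
_list     no
_definition
;Human-readable prose definition of the concept the tag denotes.
;

data_dictionary_name
_name     '_dictionary_name'
_category dictionary_header
_type     char
_list     no
_definition
;Title of the dictionary, given in the on_this_dictionary block.
;

data_namespace_prefix
_name     '_namespace_prefix'
_category dictionary_header
_type     char
_list     both
_definition
;A registered namespace prefix under which this dictionary defines
local tags.
;
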
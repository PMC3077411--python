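# Minimal English stop-list applied by the default tokenizer.
# One token per line; lines starting with '#' are ignored.
a
about
above
after
again
all
also
among
an
and
any
are
as
at
be
because
been
before
being
between
both
but
by
can
could
did
do
does
during
each
for
from
further
had
has
have
having
here
how
however
if
in
into
is
it
its
may
might
more
most
much
must
no
nor
not
of
on
only
or
other
our
over
own
same
should
so
some
such
than
that
the
their
then
there
these
they
this
those
through
to
under
until
upon
was
we
were
what
when
where
which
while
who
whom
why
will
with
within
without
would
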